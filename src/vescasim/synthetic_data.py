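"""Synthetic distributed-OSCE score generation with known true performance.

The generator follows a three-process scheme:

1. *True performance.*  Each student's unobservable performance on each
   station is the sum of a grand mean, a student ability effect, a station
   difficulty effect and a student-by-station interaction, all drawn from
   normal distributions whose standard deviations were estimated from a real
   12-station undergraduate OSCE scored on a 6-27 summed rating scale::

       true_ks = grand_mean + ability_k + station_i + interaction_ki

2. *Observed live scores.*  One examiner per (station, cohort) adds a
   systematic leniency effect (stringency = negative leniency) plus a fresh
   residual error draw; the sum is rounded to the nearest integer and clamped
   to the scale bounds, giving the mark the student would actually receive::

       score_ijk = round(true_ks + leniency_j + eps_ijk)

3. *Video linking.*  A handful of performances per station are nominated as
   "videos"; every participating examiner of that station scores every video
   of the station with their own leniency and a fresh residual.  Because the
   same performance is scored by examiners from all cohorts, these records
   cross the otherwise fully nested student/cohort structure and let a
   downstream model identify cohort severity.

Baseline between-school differences (systematic stringency offsets perfectly
negatively correlated with student ability, so that expected observed means
stay equal across schools) are applied between steps 1 and 2.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import pandas as pd

from vescasim.errors import ConfigurationError, DataError, ParameterError

__all__ = [
    "SimulationParams",
    "TruePerformance",
    "ExaminerRoster",
    "OsceDataset",
    "RECORD_COLUMNS",
    "generate_true_scores",
    "build_roster",
    "apply_baseline_difference",
    "generate_live_scores",
    "generate_video_scores",
    "assemble_dataset",
    "simulate_dataset",
]

#: Column order of the long-format score table.
RECORD_COLUMNS = [
    "student_id",
    "station_id",
    "examiner_id",
    "cohort_id",
    "is_video",
    "performance_id",
    "score",
    "residual",
]


@dataclass(frozen=True)
class SimulationParams:
    """All generating-model constants and design sizes for one condition.

    Defaults reproduce the reference study conditions: 60 students rotating
    through 12 stations, 4 examiner cohorts with one examiner per station per
    cohort (48 examiners), a 6-27 integer scale, 4 linking videos per station
    and an expected 80% examiner participation in video scoring.  Variance
    components are in raw score points.
    """

    n_students: int = 60
    n_stations: int = 12
    n_cohorts: int = 4
    examiners_per_station_per_cohort: int = 1
    scale_min: int = 6
    scale_max: int = 27
    grand_mean: float = 19.47
    student_sd: float = 1.13
    station_sd: float = 1.52
    interaction_sd: float = 1.71
    examiner_sd: float = 1.40
    residual_sd: float = 2.35
    error_divisor: float = 1.0
    n_videos: int = 4
    participation: float = 0.80
    baseline_diff: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_students < 1 or self.n_stations < 1 or self.n_cohorts < 1:
            raise ParameterError("n_students, n_stations and n_cohorts must be >= 1")
        if self.examiners_per_station_per_cohort < 1:
            raise ParameterError("examiners_per_station_per_cohort must be >= 1")
        if self.scale_max <= self.scale_min:
            raise ParameterError("scale_max must exceed scale_min")
        for name in ("student_sd", "station_sd", "interaction_sd", "examiner_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.error_divisor <= 0:
            raise ParameterError("error_divisor must be > 0")
        if not 0.0 <= self.participation <= 1.0:
            raise ParameterError("participation must lie in [0, 1]")
        if not 0.0 <= self.baseline_diff < 1.0:
            raise ParameterError("baseline_diff must lie in [0, 1)")
        if self.n_videos < 0:
            raise ParameterError("n_videos must be >= 0")
        if self.n_videos > self.n_students:
            raise ConfigurationError("n_videos cannot exceed n_students")

    @property
    def scale_range(self) -> float:
        return float(self.scale_max - self.scale_min)

    @property
    def n_examiners(self) -> int:
        return self.n_stations * self.n_cohorts * self.examiners_per_station_per_cohort

    @property
    def effective_residual_sd(self) -> float:
        """Residual SD actually applied: residual_sd / error_divisor."""
        return self.residual_sd / self.error_divisor

    def cohort_of_students(self) -> np.ndarray:
        """Balanced contiguous assignment of students to cohorts."""
        return (np.arange(self.n_students) * self.n_cohorts) // self.n_students


@dataclass
class TruePerformance:
    """Known latent performance of every student on every station.

    ``abilities`` are centred student effects (score points); ``true_scores``
    is the continuous, unrounded student-by-station matrix
    ``grand_mean + ability + station + interaction``.
    """

    abilities: np.ndarray
    station_difficulties: np.ndarray
    interactions: np.ndarray
    cohort_of_student: np.ndarray
    grand_mean: float

    @property
    def true_scores(self) -> np.ndarray:
        return (
            self.grand_mean
            + self.abilities[:, None]
            + self.station_difficulties[None, :]
            + self.interactions
        )

    @property
    def true_means(self) -> np.ndarray:
        """Per-student mean of continuous true station scores."""
        return self.true_scores.mean(axis=1)


@dataclass
class ExaminerRoster:
    """One row per examiner: station, cohort, leniency and participation.

    Leniency is in raw score points and *adds* to scores; stringency is its
    negative.  ``participates`` flags the examiners who score linking videos.
    """

    table: pd.DataFrame  # examiner_id, station_id, cohort_id, leniency, participates

    def examiner_for(self, station: int, cohort: int) -> int:
        sel = self.table[
            (self.table["station_id"] == station) & (self.table["cohort_id"] == cohort)
        ]
        if sel.empty:
            raise DataError(f"no examiner for station {station}, cohort {cohort}")
        return int(sel["examiner_id"].iloc[0])


@dataclass
class OsceDataset:
    """Long-format table of live and video score records with provenance."""

    records: pd.DataFrame
    params: SimulationParams
    seed: int | None = None
    replicate: int = 0

    @property
    def live(self) -> pd.DataFrame:
        return self.records[~self.records["is_video"]]

    @property
    def video(self) -> pd.DataFrame:
        return self.records[self.records["is_video"]]

    def to_csv(self, path) -> None:
        out = self.records.copy()
        out.insert(0, "replicate", self.replicate)
        out.drop(columns=["residual"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, params: SimulationParams | None = None) -> "OsceDataset":
        df = pd.read_csv(path)
        required = {"replicate", "student_id", "station_id", "examiner_id",
                    "cohort_id", "is_video", "performance_id", "score"}
        missing = required - set(df.columns)
        if missing:
            raise DataError(f"dataset CSV missing columns: {sorted(missing)}")
        replicate = int(df["replicate"].iloc[0]) if len(df) else 0
        records = df.drop(columns=["replicate"]).copy()
        records["is_video"] = records["is_video"].astype(bool)
        records["residual"] = np.nan
        if params is None:
            params = SimulationParams(
                scale_min=int(records["score"].min()),
                scale_max=int(records["score"].max()),
                n_students=int(records["student_id"].nunique()),
                n_stations=int(records["station_id"].nunique()),
                n_cohorts=int(records["cohort_id"].nunique()),
            )
        return cls(records=records[RECORD_COLUMNS], params=params, replicate=replicate)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.round is round-half-even; marksheets round half up.
    return np.floor(x + 0.5)


def generate_true_scores(params: SimulationParams, rng: np.random.Generator) -> TruePerformance:
    """Draw student abilities, station difficulties and interactions.

    Abilities ~ N(0, student_sd), difficulties ~ N(0, station_sd),
    interactions ~ N(0, interaction_sd); the continuous true score matrix is
    their sum plus the grand mean, left unrounded and unclamped.
    """
    abilities = rng.normal(0.0, params.student_sd, size=params.n_students)
    stations = rng.normal(0.0, params.station_sd, size=params.n_stations)
    interactions = rng.normal(
        0.0, params.interaction_sd, size=(params.n_students, params.n_stations)
    )
    return TruePerformance(
        abilities=abilities,
        station_difficulties=stations,
        interactions=interactions,
        cohort_of_student=params.cohort_of_students(),
        grand_mean=params.grand_mean,
    )


def build_roster(params: SimulationParams, rng: np.random.Generator) -> ExaminerRoster:
    """Allocate one examiner per (station, cohort) slot with random leniency.

    Leniency ~ N(0, examiner_sd); participation flags ~ Bernoulli(p).
    """
    reps = params.examiners_per_station_per_cohort
    station_ids = np.repeat(np.arange(params.n_stations), params.n_cohorts * reps)
    cohort_ids = np.tile(np.repeat(np.arange(params.n_cohorts), reps), params.n_stations)
    n = station_ids.size
    table = pd.DataFrame(
        {
            "examiner_id": np.arange(n),
            "station_id": station_ids,
            "cohort_id": cohort_ids,
            "leniency": rng.normal(0.0, params.examiner_sd, size=n),
            "participates": rng.random(n) < params.participation,
        }
    )
    return ExaminerRoster(table=table)


def apply_baseline_difference(
    perf: TruePerformance, roster: ExaminerRoster, params: SimulationParams
) -> tuple[TruePerformance, ExaminerRoster]:
    """Impose a systematic between-school stringency/ability offset.

    Cohorts are split in half: the first half of cohorts form school A, the
    rest school B.  Each school is shifted by half the stated between-school
    difference (``baseline_diff`` as a fraction of the scale range): school-A
    students gain ability, school-A examiners lose the same leniency, and
    school B receives the opposite signs.  Expected observed score means are
    therefore identical across schools while true ability differs by the full
    ``baseline_diff * scale_range`` between schools.
    """
    if params.baseline_diff == 0.0:
        return perf, roster
    if params.n_cohorts % 2 != 0:
        raise ConfigurationError("baseline differences require an even number of cohorts")
    shift = params.baseline_diff * params.scale_range / 2.0
    school_a_cohorts = np.arange(params.n_cohorts) < params.n_cohorts // 2
    student_sign = np.where(school_a_cohorts[perf.cohort_of_student], 1.0, -1.0)
    new_perf = TruePerformance(
        abilities=perf.abilities + student_sign * shift,
        station_difficulties=perf.station_difficulties.copy(),
        interactions=perf.interactions.copy(),
        cohort_of_student=perf.cohort_of_student.copy(),
        grand_mean=perf.grand_mean,
    )
    table = roster.table.copy()
    exam_sign = np.where(school_a_cohorts[table["cohort_id"].to_numpy()], 1.0, -1.0)
    table["leniency"] = table["leniency"].to_numpy() - exam_sign * shift
    return new_perf, ExaminerRoster(table=table)


def _examiner_lookup(roster: ExaminerRoster, params: SimulationParams) -> np.ndarray:
    """(station, cohort) -> examiner_id map; first listed examiner per slot."""
    lookup = np.full((params.n_stations, params.n_cohorts), -1, dtype=int)
    t = roster.table
    # reversed so the first examiner of a slot wins
    for eid, st, co in zip(
        t["examiner_id"].to_numpy()[::-1],
        t["station_id"].to_numpy()[::-1],
        t["cohort_id"].to_numpy()[::-1],
    ):
        lookup[st, co] = eid
    if (lookup < 0).any():
        missing = np.argwhere(lookup < 0)[0]
        raise DataError(f"no examiner for station {missing[0]}, cohort {missing[1]}")
    return lookup


def generate_live_scores(
    perf: TruePerformance,
    roster: ExaminerRoster,
    params: SimulationParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Score every student on every station with their cohort's examiner.

    raw = true_score + examiner leniency + eps,  eps ~ N(0, residual_sd /
    error_divisor); the recorded mark is raw rounded half-up and clamped to
    the scale bounds.
    """
    lookup = _examiner_lookup(roster, params)
    leniency = roster.table.set_index("examiner_id")["leniency"]
    students = np.repeat(np.arange(params.n_students), params.n_stations)
    stations = np.tile(np.arange(params.n_stations), params.n_students)
    cohorts = perf.cohort_of_student[students]
    examiners = lookup[stations, cohorts]
    eps = rng.normal(0.0, params.effective_residual_sd, size=students.size)
    raw = perf.true_scores[students, stations] + leniency.to_numpy()[examiners] + eps
    scores = np.clip(_round_half_up(raw), params.scale_min, params.scale_max).astype(int)
    return pd.DataFrame(
        {
            "student_id": students,
            "station_id": stations,
            "examiner_id": examiners,
            "cohort_id": cohorts,
            "is_video": False,
            "performance_id": students,
            "score": scores,
            "residual": eps,
        }
    )


def generate_video_scores(
    perf: TruePerformance,
    roster: ExaminerRoster,
    params: SimulationParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Cross-scoring of filmed performances by participating examiners.

    Per station, ``n_videos`` distinct student performances are drawn
    uniformly (any cohort); each participating examiner of that station
    scores every selected video with their own leniency and a fresh residual
    draw.  The record keeps the filmed student's identity (``student_id`` /
    ``performance_id``) and the *scoring examiner's* cohort.
    """
    if params.n_videos == 0:
        return pd.DataFrame(columns=RECORD_COLUMNS).astype(
            {"is_video": bool, "score": int}
        )
    t = roster.table
    chunks = []
    for station in range(params.n_stations):
        videos = rng.choice(params.n_students, size=params.n_videos, replace=False)
        scorers = t[(t["station_id"] == station) & t["participates"]]
        if scorers.empty:
            continue
        eids = scorers["examiner_id"].to_numpy()
        lens = scorers["leniency"].to_numpy()
        cohs = scorers["cohort_id"].to_numpy()
        vstudents = np.repeat(videos, eids.size)
        vexaminers = np.tile(eids, videos.size)
        vleniency = np.tile(lens, videos.size)
        vcohorts = np.tile(cohs, videos.size)
        eps = rng.normal(0.0, params.effective_residual_sd, size=vstudents.size)
        raw = perf.true_scores[vstudents, station] + vleniency + eps
        scores = np.clip(_round_half_up(raw), params.scale_min, params.scale_max).astype(int)
        chunks.append(
            pd.DataFrame(
                {
                    "student_id": vstudents,
                    "station_id": station,
                    "examiner_id": vexaminers,
                    "cohort_id": vcohorts,
                    "is_video": True,
                    "performance_id": vstudents,
                    "score": scores,
                    "residual": eps,
                }
            )
        )
    if not chunks:
        return pd.DataFrame(columns=RECORD_COLUMNS).astype({"is_video": bool, "score": int})
    return pd.concat(chunks, ignore_index=True)[RECORD_COLUMNS]


def assemble_dataset(
    live: pd.DataFrame,
    video: pd.DataFrame,
    params: SimulationParams,
    seed: int | None = None,
    replicate: int = 0,
) -> OsceDataset:
    """Concatenate live and video records and validate structural invariants."""
    records = pd.concat([live, video], ignore_index=True) if len(video) else live.copy()
    records = records.reset_index(drop=True)[RECORD_COLUMNS]
    n_live = int((~records["is_video"]).sum())
    if n_live != params.n_students * params.n_stations:
        raise DataError(
            f"expected {params.n_students * params.n_stations} live records, got {n_live}"
        )
    scores = records["score"]
    if (scores < params.scale_min).any() or (scores > params.scale_max).any():
        raise DataError("scores outside scale bounds")
    live_keys = records.loc[~records["is_video"], ["student_id", "station_id", "examiner_id"]]
    if live_keys.duplicated().any():
        raise DataError("duplicate live (student, station, examiner) records")
    vid = records[records["is_video"]]
    if len(vid):
        per_examiner = vid.groupby("examiner_id").size()
        if (per_examiner != params.n_videos).any():
            raise DataError("a participating examiner does not have exactly n_videos video records")
    return OsceDataset(records=records, params=params, seed=seed, replicate=replicate)


def simulate_dataset(
    params: SimulationParams,
    rng: np.random.Generator | int | None = None,
    replicate: int = 0,
) -> tuple[TruePerformance, ExaminerRoster, OsceDataset]:
    """Run the full three-process generation pipeline for one replicate."""
    seed = None
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = params.seed if rng is None else int(rng)
        rng = np.random.default_rng(seed)
    perf = generate_true_scores(params, rng)
    roster = build_roster(params, rng)
    perf, roster = apply_baseline_difference(perf, roster, params)
    live = generate_live_scores(perf, roster, params, rng)
    video = generate_video_scores(perf, roster, params, rng)
    dataset = assemble_dataset(live, video, params, seed=seed, replicate=replicate)
    return perf, roster, dataset
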