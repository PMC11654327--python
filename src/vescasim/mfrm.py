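"""Three-facet Many-Facet Rasch rating-scale model fitted by JMLE.

The model for an observation of student *n* on station *i* scored by an
examiner of cohort *j* in ordered category *k* is, on adjacent-category
log-odds::

    log(P_nijk / P_nij(k-1)) = B_n - D_i - C_j - F_k

where ``B_n`` is student ability, ``D_i`` station difficulty, ``C_j`` the
severity of examiner-cohort *j*, and ``F_k`` the common rating-scale step
threshold between categories *k-1* and *k* (one shared threshold set across
stations).  All parameters are on the logit scale.

Estimation is joint maximum likelihood (JMLE): alternating damped
Newton-Raphson updates of each facet and of the thresholds until the largest
absolute logit change falls below a tolerance.  Identification follows rater
-measurement convention: station difficulties, cohort severities and
thresholds are each centred at zero; when the observation graph does not link
the cohorts (no cross-cohort video scores) cohort severities are anchored at
zero instead, which also makes the zero-video design well defined.

The adjusted ("fair average") score of a student is the model-expected raw
score with station difficulty and cohort severity both at their reference
value of zero — i.e. the score the student would be expected to obtain from a
perfectly average station seen by a perfectly average examiner cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from vescasim.errors import ModelError
from vescasim.synthetic_data import OsceDataset

__all__ = [
    "MfrmConfig",
    "MfrmEstimates",
    "AdjustedScores",
    "category_probabilities",
    "expected_score",
    "check_connectivity",
    "fit_jmle",
    "adjusted_scores",
]

_MAX_STEP = 1.0  # logits; damping cap on any single Newton step


@dataclass(frozen=True)
class MfrmConfig:
    """Estimation controls for the JMLE fit.

    ``extreme_score_adjustment`` is the fractional score-point shrinkage
    applied to all-minimum / all-maximum raw totals so that the corresponding
    measures stay finite (the conventional value is 0.3).
    """

    max_iterations: int = 100
    convergence_tol: float = 1e-3
    extreme_score_adjustment: float = 0.3
    anchor_policy: str = "auto"  # "auto" | "cohorts_at_zero"
    separate_video_persons: bool = True

    def __post_init__(self) -> None:
        if self.convergence_tol <= 0:
            raise ModelError("convergence_tol must be > 0")
        if not 0.0 < self.extreme_score_adjustment < 0.5:
            raise ModelError("extreme_score_adjustment must lie in (0, 0.5)")
        if self.anchor_policy not in ("auto", "cohorts_at_zero"):
            raise ModelError(f"unknown anchor_policy {self.anchor_policy!r}")


@dataclass
class MfrmEstimates:
    """Fitted facet measures (logits), thresholds and diagnostics."""

    student_ids: np.ndarray
    student_measures: np.ndarray
    student_se: np.ndarray
    station_ids: np.ndarray
    station_difficulties: np.ndarray
    cohort_ids: np.ndarray
    cohort_severities: np.ndarray
    thresholds: np.ndarray  # F_k for k = 1..K-1, mean 0
    category_values: np.ndarray  # raw scores the K categories map to
    converged: bool
    iterations: int
    connected: bool
    subset_labels: dict = field(default_factory=dict)
    cohorts_anchored: bool = False

    def to_frame(self) -> pd.DataFrame:
        """Long-format `facet,element_id,measure,se` table."""
        rows = []
        for sid, m, se in zip(self.student_ids, self.student_measures, self.student_se):
            rows.append(("student", int(sid), float(m), float(se)))
        for sid, m in zip(self.station_ids, self.station_difficulties):
            rows.append(("station", int(sid), float(m), np.nan))
        for cid, m in zip(self.cohort_ids, self.cohort_severities):
            rows.append(("cohort", int(cid), float(m), np.nan))
        for k, f in enumerate(self.thresholds, start=1):
            rows.append(("threshold", k, float(f), np.nan))
        return pd.DataFrame(rows, columns=["facet", "element_id", "measure", "se"])


@dataclass
class AdjustedScores:
    """Per-student fair-average adjusted score on the raw scale."""

    table: pd.DataFrame  # student_id, measure, adjusted_score

    def for_student(self, student_id: int) -> float:
        sel = self.table[self.table["student_id"] == student_id]
        if sel.empty:
            raise ModelError(f"no adjusted score for student {student_id}")
        return float(sel["adjusted_score"].iloc[0])


def _step_logits(thresholds: np.ndarray) -> np.ndarray:
    """Cumulative threshold sums S_k = sum_{h<=k} F_h with S_0 = 0."""
    return np.concatenate([[0.0], np.cumsum(thresholds)])


def category_probabilities(
    measure: float,
    difficulty: float,
    severity: float,
    thresholds: np.ndarray,
) -> np.ndarray:
    """Probability of each of the K ordered categories.

    Adjacent-category log-odds equal ``measure - difficulty - severity -
    F_k``; the unnormalised log-probability of category k is ``k * theta -
    S_k`` with ``S_k`` the cumulative threshold sum, normalised by softmax.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    n_cat = thresholds.size + 1
    if n_cat < 2:
        raise ModelError("at least 2 categories are required")
    theta = measure - difficulty - severity
    logits = np.arange(n_cat) * theta - _step_logits(thresholds)
    logits -= logits.max()
    p = np.exp(logits)
    return p / p.sum()


def expected_score(
    measure: float,
    difficulty: float,
    severity: float,
    thresholds: np.ndarray,
    category_values: np.ndarray,
) -> float:
    """Probability-weighted mean of the category values (strictly increasing
    in ``measure``)."""
    category_values = np.asarray(category_values, dtype=float)
    if np.any(np.diff(category_values) <= 0):
        raise ModelError("category_values must be strictly increasing")
    p = category_probabilities(measure, difficulty, severity, thresholds)
    if p.size != category_values.size:
        raise ModelError("category_values length must be number of thresholds + 1")
    return float(p @ category_values)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def check_connectivity(dataset: OsceDataset) -> tuple[bool, dict]:
    """Whether cohort severities are identifiable from the observation graph.

    Builds the bipartite student-cohort graph with an edge for every score
    record (a video record links the filmed student to the *scoring*
    examiner's cohort).  Severity differences between two cohorts are
    identifiable only if the cohorts fall in the same connected component,
    which at generation defaults requires cross-cohort video scoring.

    Returns ``(connected, labels)`` where ``connected`` is True iff all
    cohorts share one component and ``labels`` maps ``("student", id)`` and
    ``("cohort", id)`` to 0-based subset labels.
    """
    df = dataset.records
    if df.empty:
        raise ModelError("empty dataset")
    students = np.unique(df["student_id"].to_numpy())
    cohorts = np.unique(df["cohort_id"].to_numpy())
    s_index = {s: i for i, s in enumerate(students)}
    c_index = {c: len(students) + i for i, c in enumerate(cohorts)}
    uf = _UnionFind(len(students) + len(cohorts))
    for s, c in df[["student_id", "cohort_id"]].drop_duplicates().itertuples(index=False):
        uf.union(s_index[s], c_index[c])
    roots: dict[int, int] = {}
    labels: dict = {}
    for s in students:
        r = uf.find(s_index[s])
        labels[("student", int(s))] = roots.setdefault(r, len(roots))
    for c in cohorts:
        r = uf.find(c_index[c])
        labels[("cohort", int(c))] = roots.setdefault(r, len(roots))
    cohort_roots = {labels[("cohort", int(c))] for c in cohorts}
    return len(cohort_roots) == 1, labels


def _facet_update(
    idx: np.ndarray,
    n_elem: int,
    k_obs: np.ndarray,
    expected: np.ndarray,
    variance: np.ndarray,
    targets: np.ndarray,
) -> np.ndarray:
    """Damped Newton step per facet element from score residuals."""
    e_sum = np.bincount(idx, weights=expected, minlength=n_elem)
    v_sum = np.bincount(idx, weights=variance, minlength=n_elem)
    step = np.zeros(n_elem)
    ok = v_sum > 1e-10
    step[ok] = (targets[ok] - e_sum[ok]) / v_sum[ok]
    return np.clip(step, -_MAX_STEP, _MAX_STEP)


def _extreme_targets(
    idx: np.ndarray, n_elem: int, k_obs: np.ndarray, k_max: int, adj: float
) -> np.ndarray:
    """Raw category totals per element, with extreme totals pulled inward."""
    totals = np.bincount(idx, weights=k_obs.astype(float), minlength=n_elem)
    counts = np.bincount(idx, minlength=n_elem)
    top = counts * k_max
    targets = totals.copy()
    targets[totals >= top] = top[totals >= top] - adj
    targets[totals <= 0] = adj
    return targets


def fit_jmle(dataset: OsceDataset, config: MfrmConfig | None = None) -> MfrmEstimates:
    """Joint maximum likelihood fit of the three-facet rating-scale model.

    Categories are recoded to the observed distinct raw scores (unobserved
    extreme categories are dropped and unobserved interior categories merge
    with their lower neighbour), so with K observed score values the model
    has K-1 free thresholds; fair averages are computed back on the observed
    raw values.  Alternating damped Newton-Raphson updates run until the
    largest absolute parameter change is below ``convergence_tol`` or
    ``max_iterations`` is reached (the fit is then flagged unconverged but
    still returned).
    """
    if config is None:
        config = MfrmConfig()
    df = dataset.records
    if df.empty:
        raise ModelError("cannot fit an empty dataset")

    # Video scores link cohorts but must not feed back into the filmed
    # student's own measure, so each filmed performance becomes a separate
    # person element keyed by (station, student); live students keep their
    # own identity.
    raw_students = df["student_id"].to_numpy()
    if config.separate_video_persons:
        is_video = df["is_video"].to_numpy()
        stations_raw = df["station_id"].to_numpy()
        person_keys = np.where(
            is_video,
            -(stations_raw.astype(np.int64) * (raw_students.max() + 2) + raw_students + 2),
            raw_students,
        )
    else:
        person_keys = raw_students
    person_ids, s_idx_all = np.unique(person_keys, return_inverse=True)

    student_ids, s_idx = person_ids, s_idx_all
    # live-student elements; video-performance elements (negative keys) are
    # nuisance parameters and are not reported
    live_elements = person_ids >= 0
    station_ids, i_idx = np.unique(df["station_id"].to_numpy(), return_inverse=True)
    cohort_ids, c_idx = np.unique(df["cohort_id"].to_numpy(), return_inverse=True)
    scores = df["score"].to_numpy()
    values = np.unique(scores)
    n_cat = values.size

    connected, labels = check_connectivity(dataset)
    anchor_cohorts = config.anchor_policy == "cohorts_at_zero" or (
        config.anchor_policy == "auto" and not connected
    )

    n_s, n_i, n_c = student_ids.size, station_ids.size, cohort_ids.size

    if n_cat == 1:
        # Degenerate constant dataset: nothing to estimate.
        return MfrmEstimates(
            student_ids=student_ids[live_elements],
            student_measures=np.zeros(int(live_elements.sum())),
            student_se=np.full(int(live_elements.sum()), np.inf),
            station_ids=station_ids,
            station_difficulties=np.zeros(n_i),
            cohort_ids=cohort_ids,
            cohort_severities=np.zeros(n_c),
            thresholds=np.zeros(0),
            category_values=values.astype(float),
            converged=True,
            iterations=0,
            connected=connected,
            subset_labels=labels,
            cohorts_anchored=True,
        )

    k_obs = np.searchsorted(values, scores)
    k_max = n_cat - 1
    kvec = np.arange(n_cat, dtype=float)

    adj = config.extreme_score_adjustment
    t_students = _extreme_targets(s_idx, n_s, k_obs, k_max, adj)
    t_stations = _extreme_targets(i_idx, n_i, k_obs, k_max, adj)
    t_cohorts = _extreme_targets(c_idx, n_c, k_obs, k_max, adj)
    # observed counts of categories >= k, for threshold updates
    cat_counts = np.bincount(k_obs, minlength=n_cat).astype(float)
    obs_ge = cat_counts[::-1].cumsum()[::-1]  # index k: count of obs >= k

    B = np.zeros(n_s)
    D = np.zeros(n_i)
    C = np.zeros(n_c)
    F = np.zeros(k_max)

    # subset labels on the person/cohort bipartite observation graph, for
    # per-subset centring of cohort severities (only relevant if estimated)
    uf = _UnionFind(n_s + n_c)
    for p_el, c_el in set(zip(s_idx.tolist(), c_idx.tolist())):
        uf.union(p_el, n_s + c_el)
    roots: dict[int, int] = {}
    person_subset = np.array([roots.setdefault(uf.find(i), len(roots)) for i in range(n_s)])
    cohort_subset = np.array(
        [roots.setdefault(uf.find(n_s + j), len(roots)) for j in range(n_c)]
    )

    def probs() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        theta = B[s_idx] - D[i_idx] - C[c_idx]
        logit = theta[:, None] * kvec[None, :] - _step_logits(F)[None, :]
        logit -= logit.max(axis=1, keepdims=True)
        p = np.exp(logit)
        p /= p.sum(axis=1, keepdims=True)
        e = p @ kvec
        v = p @ (kvec ** 2) - e ** 2
        return p, e, v

    converged = False
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        max_change = 0.0

        _, e, v = probs()
        dB = _facet_update(s_idx, n_s, k_obs, e, v, t_students)
        B += dB
        max_change = max(max_change, float(np.abs(dB).max(initial=0.0)))

        _, e, v = probs()
        dD = _facet_update(i_idx, n_i, k_obs, e, v, t_stations)
        D -= dD
        max_change = max(max_change, float(np.abs(dD).max(initial=0.0)))

        if not anchor_cohorts:
            _, e, v = probs()
            dC = _facet_update(c_idx, n_c, k_obs, e, v, t_cohorts)
            C -= dC
            max_change = max(max_change, float(np.abs(dC).max(initial=0.0)))

        # Thresholds are mutually coupled (the Hessian is far from diagonal
        # for adjacent categories), so they get a joint Newton step:
        # d2L/dF_k dF_l = -sum_o Cov(1{X>=k}, 1{X>=l}).
        p, _, _ = probs()
        p_ge = np.cumsum(p[:, ::-1], axis=1)[:, ::-1][:, 1:]  # col k-1: P(X >= k)
        g = p_ge.sum(axis=0) - obs_ge[1:]
        q = p_ge.sum(axis=0)
        idx = np.arange(k_max)
        hess = q[np.maximum.outer(idx, idx)] - p_ge.T @ p_ge
        hess[np.diag_indices_from(hess)] += 1e-8
        dF = np.clip(np.linalg.solve(hess, g), -_MAX_STEP, _MAX_STEP)
        F += dF
        max_change = max(max_change, float(np.abs(dF).max(initial=0.0)))

        # identification: centre thresholds, stations, cohorts; compensate B
        f_mean = F.mean()
        F -= f_mean
        B -= f_mean  # theta - F_k invariant
        d_mean = D.mean()
        D -= d_mean
        B -= d_mean
        if not anchor_cohorts:
            for sub in np.unique(cohort_subset):
                c_mean = C[cohort_subset == sub].mean()
                C[cohort_subset == sub] -= c_mean
                B[person_subset == sub] -= c_mean

        if max_change < config.convergence_tol:
            converged = True
            break

    _, e, v = probs()
    v_sum = np.bincount(s_idx, weights=v, minlength=n_s)
    student_se = np.where(v_sum > 1e-10, 1.0 / np.sqrt(np.maximum(v_sum, 1e-10)), np.inf)

    return MfrmEstimates(
        student_ids=student_ids[live_elements],
        student_measures=B[live_elements],
        student_se=student_se[live_elements],
        station_ids=station_ids,
        station_difficulties=D,
        cohort_ids=cohort_ids,
        cohort_severities=C,
        thresholds=F,
        category_values=values.astype(float),
        converged=converged,
        iterations=iterations,
        connected=connected,
        subset_labels=labels,
        cohorts_anchored=anchor_cohorts,
    )


def adjusted_scores(estimates: MfrmEstimates) -> AdjustedScores:
    """Fair-average adjusted score per student.

    The fair average evaluates the model-expected raw score at station
    difficulty 0 and cohort severity 0, removing cohort severity and station
    effects by construction.
    """
    values = estimates.category_values
    if values.size == 1:
        adj = np.full(estimates.student_ids.size, float(values[0]))
    else:
        theta = estimates.student_measures
        kvec = np.arange(values.size, dtype=float)
        logit = theta[:, None] * kvec[None, :] - _step_logits(estimates.thresholds)[None, :]
        logit -= logit.max(axis=1, keepdims=True)
        p = np.exp(logit)
        p /= p.sum(axis=1, keepdims=True)
        adj = p @ values
    table = pd.DataFrame(
        {
            "student_id": estimates.student_ids,
            "measure": estimates.student_measures,
            "adjusted_score": adj,
        }
    )
    return AdjustedScores(table=table)
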