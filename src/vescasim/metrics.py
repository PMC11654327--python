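"""Accuracy metrics for score adjustment.

For each student three quantities are computed against the known continuous
true performance mean:

- observed score error  A = |observed mean - true mean|
- adjusted score error  B = |fair average - true mean|
- score adjustment      C = |fair average - observed mean|

A condition is summarised by the pooled error ratio ``ErR = mean(B) /
mean(A)`` (values below 1 mean adjustment helped) and by ``pAcc``, the
proportion of student-replicates with strictly ``B < A``.  The threshold
analysis bins students by adjustment size as a percentage of the scale range
and asks from which bin upward adjustment is reliably beneficial
(pAcc >= 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from vescasim.errors import DataError
from vescasim.mfrm import AdjustedScores
from vescasim.synthetic_data import OsceDataset, SimulationParams, TruePerformance

__all__ = [
    "StudentAccuracy",
    "ConditionSummary",
    "AdjustmentBinTable",
    "ACCURACY_COLUMNS",
    "score_student_accuracy",
    "summarize_condition",
    "rq4_tabulate",
]

ACCURACY_COLUMNS = [
    "student_id",
    "true_mean",
    "observed_mean",
    "adjusted",
    "observed_error",
    "adjusted_error",
    "adjustment",
    "improved",
]

#: Adjustment-size bin lower edges in % of scale range: [0,1), ..., [8,9), >=9.
ADJUSTMENT_BIN_EDGES = np.arange(0, 10, dtype=float)

#: Accuracy-change bin edges in % of scale range; change = (A - B), so
#: positive means the adjusted score is more accurate.  Interior edges are
#: right-closed on the non-positive side so a tie (change 0) lands in the
#: "not improved" bin (-2, 0].
ACCURACY_CHANGE_EDGES = np.array([-6.0, -4.0, -2.0, 0.0, 2.0, 4.0, 6.0])


@dataclass
class StudentAccuracy:
    """Per-student accuracy quantities for one replicate."""

    student_id: int
    true_mean: float
    observed_mean: float
    adjusted: float
    observed_error: float
    adjusted_error: float
    adjustment: float
    improved: bool


@dataclass
class ConditionSummary:
    """Pooled accuracy aggregates for one simulated condition."""

    params: SimulationParams
    n_replicates: int
    mean_observed_error: float
    sd_observed_error: float
    mean_adjusted_error: float
    sd_adjusted_error: float
    error_ratio: float
    p_acc: float
    n_students_pooled: int = 0
    n_converged: int = 0
    condition_id: str = ""

    def as_row(self) -> dict:
        p = self.params
        return {
            "condition_id": self.condition_id,
            "n_videos": p.n_videos,
            "participation": p.participation,
            "baseline_diff": p.baseline_diff,
            "n_stations": p.n_stations,
            "error_divisor": p.error_divisor,
            "n_replicates": self.n_replicates,
            "mean_obs_err": self.mean_observed_error,
            "sd_obs_err": self.sd_observed_error,
            "mean_adj_err": self.mean_adjusted_error,
            "sd_adj_err": self.sd_adjusted_error,
            "error_ratio": self.error_ratio,
            "p_acc": self.p_acc,
        }


@dataclass
class AdjustmentBinTable:
    """Cross-tabulation of adjustment size versus accuracy change.

    ``counts`` is (n adjustment bins) x (n accuracy-change bins);
    ``bin_p_acc`` is pAcc within each adjustment bin; ``threshold_bin`` is
    the lower edge (in % of scale) of the smallest supported adjustment bin
    from which upward every supported bin reaches pAcc >= 0.8, or None.
    """

    adjustment_bin_edges: np.ndarray
    accuracy_change_edges: np.ndarray
    counts: np.ndarray
    bin_counts: np.ndarray
    bin_p_acc: np.ndarray
    threshold_bin: float | None
    p_acc_target: float = 0.8
    min_bin_count: int = 20

    def to_frame(self) -> pd.DataFrame:
        cols = (
            ["<-6"]
            + [f"({lo:g},{hi:g}]" for lo, hi in zip(self.accuracy_change_edges[:-1],
                                                    self.accuracy_change_edges[1:])]
            + [">6"]
        )
        idx = [f"[{e:g},{e + 1:g})" for e in self.adjustment_bin_edges[:-1]] + [">=9"]
        df = pd.DataFrame(self.counts, index=idx, columns=cols)
        df.index.name = "adjustment_pct"
        df["n"] = self.bin_counts
        df["p_acc"] = self.bin_p_acc
        return df


def _as_accuracy_frame(acc) -> pd.DataFrame:
    if isinstance(acc, pd.DataFrame):
        return acc
    return pd.DataFrame([a.__dict__ for a in acc])


def score_student_accuracy(
    perf: TruePerformance,
    dataset: OsceDataset,
    adj: AdjustedScores,
) -> pd.DataFrame:
    """Per-student accuracy table for one replicate.

    True means use the continuous (unrounded) true station scores; observed
    means use live scores only (video scores never contribute to a student's
    reported score).  ``improved`` is strict: ties count as not improved.
    """
    live = dataset.live
    observed = live.groupby("student_id")["score"].mean()
    adjusted = adj.table.set_index("student_id")["adjusted_score"]
    student_ids = observed.index.to_numpy()
    missing = set(student_ids) - set(adjusted.index)
    if missing:
        raise DataError(f"missing adjusted scores for students {sorted(missing)[:5]}")
    true_means = perf.true_means[student_ids]
    obs = observed.to_numpy()
    adj_scores = adjusted.loc[student_ids].to_numpy()
    observed_error = np.abs(obs - true_means)
    adjusted_error = np.abs(adj_scores - true_means)
    return pd.DataFrame(
        {
            "student_id": student_ids,
            "true_mean": true_means,
            "observed_mean": obs,
            "adjusted": adj_scores,
            "observed_error": observed_error,
            "adjusted_error": adjusted_error,
            "adjustment": np.abs(adj_scores - obs),
            "improved": adjusted_error < observed_error,
        }
    )


def summarize_condition(
    accuracy_tables: Iterable[pd.DataFrame],
    params: SimulationParams,
    condition_id: str = "",
    n_converged: int | None = None,
) -> ConditionSummary:
    """Pool per-replicate accuracy tables into one condition summary.

    Students are pooled across replicates before aggregation: the error
    ratio is the ratio of pooled means (not the mean of per-replicate
    ratios) and pAcc is the pooled improved fraction.
    """
    tables = [_as_accuracy_frame(t) for t in accuracy_tables]
    if not tables:
        raise DataError("at least one replicate is required")
    pooled = pd.concat(tables, ignore_index=True)
    mean_obs = float(pooled["observed_error"].mean())
    mean_adj = float(pooled["adjusted_error"].mean())
    if mean_obs == 0.0:
        raise DataError("pooled observed error is zero; error ratio undefined")
    return ConditionSummary(
        params=params,
        n_replicates=len(tables),
        mean_observed_error=mean_obs,
        sd_observed_error=float(pooled["observed_error"].std(ddof=1)),
        mean_adjusted_error=mean_adj,
        sd_adjusted_error=float(pooled["adjusted_error"].std(ddof=1)),
        error_ratio=mean_adj / mean_obs,
        p_acc=float(pooled["improved"].mean()),
        n_students_pooled=len(pooled),
        n_converged=len(tables) if n_converged is None else n_converged,
        condition_id=condition_id,
    )


def rq4_tabulate(
    accuracy,
    scale_range: float,
    p_acc_target: float = 0.8,
    min_bin_count: int = 20,
) -> AdjustmentBinTable:
    """Bin students by adjustment size and locate a reliability threshold.

    Adjustment size and accuracy change (observed error minus adjusted
    error) are expressed as percentages of the scale range and binned as
    [0,1%), ..., [8,9%), >=9% and (<-6), (-6,-4], (-4,-2], (-2,0], (0,2],
    (2,4], (4,6], (>6) respectively.  The threshold is the lower edge of the
    smallest adjustment bin with at least ``min_bin_count`` students such
    that that bin and every equally supported higher bin reach
    ``pAcc >= p_acc_target``; thinner bins are too noisy to certify a
    threshold and are ignored.  None is returned when no such bin exists.
    """
    df = _as_accuracy_frame(accuracy)
    if df.empty:
        raise DataError("rq4_tabulate requires a nonempty accuracy table")
    adj_pct = df["adjustment"].to_numpy() / scale_range * 100.0
    change_pct = (df["observed_error"] - df["adjusted_error"]).to_numpy() / scale_range * 100.0

    n_adj_bins = ADJUSTMENT_BIN_EDGES.size  # [0,1) ... [8,9), >=9
    adj_bin = np.minimum(np.floor(adj_pct).astype(int), n_adj_bins - 1)
    # right-closed interior bins so a change of exactly 0 is "not improved"
    chg_bin = np.digitize(change_pct, ACCURACY_CHANGE_EDGES, right=True)
    n_chg_bins = ACCURACY_CHANGE_EDGES.size + 1

    counts = np.zeros((n_adj_bins, n_chg_bins), dtype=int)
    np.add.at(counts, (adj_bin, chg_bin), 1)

    improved = df["improved"].to_numpy()
    bin_counts = np.bincount(adj_bin, minlength=n_adj_bins)
    bin_improved = np.bincount(adj_bin, weights=improved.astype(float), minlength=n_adj_bins)
    with np.errstate(invalid="ignore"):
        bin_p_acc = np.where(bin_counts > 0, bin_improved / np.maximum(bin_counts, 1), np.nan)

    threshold: float | None = None
    supported = bin_counts >= min_bin_count
    meets = supported & (bin_p_acc >= p_acc_target)
    for b in range(n_adj_bins):
        if not supported[b]:
            continue
        above = supported[b:]
        if above.any() and meets[b:][above].all():
            threshold = float(ADJUSTMENT_BIN_EDGES[b])
            break
    return AdjustmentBinTable(
        adjustment_bin_edges=ADJUSTMENT_BIN_EDGES.copy(),
        accuracy_change_edges=ACCURACY_CHANGE_EDGES.copy(),
        counts=counts,
        bin_counts=bin_counts,
        bin_p_acc=bin_p_acc,
        threshold_bin=threshold,
        p_acc_target=p_acc_target,
        min_bin_count=min_bin_count,
    )
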