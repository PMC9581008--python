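"""Per-peptide two-cohort differential reactivity.

For every peptide a two-sided Mann-Whitney U test compares the control
and treatment intensity distributions (null: identical distributions).
Raw p-values are corrected across all peptides jointly with the
Benjamini-Hochberg step-up procedure; the user-facing FDR thresholds
(0.01, 0.05, 0.10, 0.25) are deliberately tolerant because this stage
is a candidate screen, not a confirmation.  The effect size is
"delta RFU": treatment mean minus control mean.

The rank-cutoff subset rules select the peptides that feed heat maps,
swarm plots, and dendrograms: the k lowest adjusted p-values, the k
largest (direction up) or smallest (down) effect sizes, and the k most
extreme effects among peptides passing the FDR threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .arrayio import SynopticTable
from .preprocess import IntensityMatrix

RANK_CUTOFFS = (20, 50, 100)
DIRECTIONS = ("up", "down", "any")
FDR_LEVELS = (0.01, 0.05, 0.10, 0.25)

# exact permutation null is used up to this combined sample count
# (tie-free); beyond it the normal approximation with tie and
# continuity corrections applies
EXACT_N_MAX = 12


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    Uses the exact permutation distribution when the combined sample
    size is <= 12 and values are tie-free, else the normal approximation
    with tie correction and continuity correction.  Completely constant
    data across both groups yields p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups need at least one observation")
    if min(x.size, y.size) < 3:
        warnings.warn(
            f"group sizes {x.size} and {y.size}: U test has negligible power below 3",
            stacklevel=2,
        )
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical in both groups; p set to 1", stacklevel=2)
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= EXACT_N_MAX and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), min(float(res.pvalue), 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    bad = np.where(~((p >= 0) & (p <= 1)))[0]
    if bad.size:
        raise ValueError(
            f"p-values outside [0, 1] at indices {bad[:10].tolist()}"
        )
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def build_synoptic_table(matrix: IntensityMatrix) -> SynopticTable:
    """Per-peptide statistics table from a (normalized) intensity matrix.

    Means and variances are per cohort (variance unbiased, n-1 with a
    zero fallback for singleton cohorts); delta RFU is treatment mean
    minus control mean; adjusted p-values come from a single BH pass
    over all peptides.
    """
    control = matrix.cohort_samples("control")
    treatment = matrix.cohort_samples("treatment")
    if not control or not treatment:
        raise ValueError("matrix must contain both cohorts")
    V = matrix.values
    C = V[control].to_numpy(dtype=float)
    T = V[treatment].to_numpy(dtype=float)

    def _var(block: np.ndarray) -> np.ndarray:
        if block.shape[1] < 2:
            return np.zeros(block.shape[0])
        return block.var(axis=1, ddof=1)

    p_raw = np.empty(len(V))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(len(V)):
            _, p_raw[i] = mann_whitney_u(C[i], T[i])
    data = pd.DataFrame(
        {
            "spot_id": V.index.astype(str),
            "sequence": matrix.sequences.reindex(V.index).astype(str).to_numpy(),
        }
    )
    for s in control + treatment:
        data[s] = V[s].to_numpy()
    data["control_mean"] = C.mean(axis=1)
    data["control_var"] = _var(C)
    data["treatment_mean"] = T.mean(axis=1)
    data["treatment_var"] = _var(T)
    data["delta_rfu"] = data["treatment_mean"] - data["control_mean"]
    data["p_raw"] = p_raw
    data["p_adj"] = bh_adjust(p_raw)
    data = data.reset_index(drop=True)
    return SynopticTable(
        data=data, control_samples=list(control), treatment_samples=list(treatment)
    )


@dataclass(frozen=True)
class SubsetSpec:
    """Rank-cutoff subset rule: size, direction of change, FDR threshold."""

    cutoff: int = 50
    direction: str = "any"
    fdr: float = 0.05

    def __post_init__(self) -> None:
        if self.cutoff not in RANK_CUTOFFS:
            raise ValueError(f"cutoff must be one of {RANK_CUTOFFS}, got {self.cutoff}")
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )
        if not any(np.isclose(self.fdr, f) for f in FDR_LEVELS):
            raise ValueError(f"fdr must be one of {FDR_LEVELS}, got {self.fdr}")


@dataclass
class SubsetSelection:
    """The three peptide lists driving subset-restricted plots (spot IDs)."""

    by_p: list[str]
    by_effect: list[str]
    by_both: list[str]


def _top_ids(df: pd.DataFrame, sort_cols, ascending, k: int) -> list[str]:
    # stable sort; |delta| descending and spot_id ascending break ties
    ordered = df.sort_values(
        sort_cols + ["abs_delta", "spot_id"],
        ascending=list(ascending) + [False, True],
        kind="mergesort",
    )
    return ordered["spot_id"].head(k).tolist()


def select_subset(table: SynopticTable, spec: SubsetSpec) -> SubsetSelection:
    """Apply the rank-cutoff rules to a synoptic table.

    Direction ``down``: by_p = the k lowest adjusted p-values among
    peptides with negative delta RFU; by_effect = the k smallest (most
    negative) delta RFU; by_both = the k smallest delta RFU among
    peptides with adjusted p below the FDR threshold.  ``up`` mirrors
    this on positive deltas / largest effects.  ``any`` ignores sign and
    ranks by_effect on \\|delta RFU\\|.  Lists shorter than k are returned
    as-is.
    """
    if len(table) == 0:
        raise ValueError("synoptic table is empty")
    df = table.data[["spot_id", "delta_rfu", "p_adj"]].copy()
    df["abs_delta"] = df["delta_rfu"].abs()
    k = spec.cutoff
    if spec.direction == "down":
        pool = df[df["delta_rfu"] < 0]
        by_p = _top_ids(pool, ["p_adj"], [True], k)
        by_effect = _top_ids(df, ["delta_rfu"], [True], k)
        sig = df[df["p_adj"] < spec.fdr]
        by_both = _top_ids(sig[sig["delta_rfu"] < 0], ["delta_rfu"], [True], k)
    elif spec.direction == "up":
        pool = df[df["delta_rfu"] > 0]
        by_p = _top_ids(pool, ["p_adj"], [True], k)
        by_effect = _top_ids(df, ["delta_rfu"], [False], k)
        sig = df[df["p_adj"] < spec.fdr]
        by_both = _top_ids(sig[sig["delta_rfu"] > 0], ["delta_rfu"], [False], k)
    else:
        by_p = _top_ids(df, ["p_adj"], [True], k)
        by_effect = _top_ids(df, ["abs_delta"], [False], k)
        sig = df[df["p_adj"] < spec.fdr]
        by_both = _top_ids(sig, ["abs_delta"], [False], k)
    return SubsetSelection(by_p=by_p, by_effect=by_effect, by_both=by_both)
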