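"""Spot intensities -> per-peptide values -> cross-sample matrix.

Three intensity modes are supported.  ``foreground`` uses the raw spot
foreground f_l.  ``background_subtract`` removes the local optical bias:
f_l - b_l.  ``background_scale`` additionally corrects for spatial
variation in scanner background by rescaling both terms with the ratio
of the local background b_l to the array-wide median background b_m:

    f_s = f_l * b_m / b_l - b_m

which collapses to plain subtraction when b_l == b_m.  Negative results
are retained: clipping would distort quantile normalization, and the
downstream rank test is indifferent to sign.

Replicate spots of the same peptide (arrays are typically printed in
triplicate) are aggregated by median before statistics; pass
``aggregate=False`` to test every spot independently instead.
"""

from __future__ import annotations

import enum
import logging
import re
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .arrayio import ArraySample, ArrayValidationError

logger = logging.getLogger(__name__)


class IntensityMode(str, enum.Enum):
    FOREGROUND = "foreground"
    BACKGROUND_SUBTRACT = "background_subtract"
    BACKGROUND_SCALE = "background_scale"


# Pattern stripped from spot IDs to name a replicate group's representative
# spot; matches a trailing ".<n>" replicate suffix.
DEFAULT_REPLICATE_SUFFIX = r"\.\d+$"


@dataclass(frozen=True)
class Provenance:
    intensity_mode: str
    aggregated: bool
    normalization: str = "raw"


@dataclass
class IntensityMatrix:
    """Peptide x sample intensity matrix.

    ``values``: DataFrame with peptide IDs as index and sample IDs as
    columns, control block first then treatment block.  ``cohorts`` maps
    each sample ID to its cohort.  ``sequences`` maps peptide ID to the
    peptide's amino-acid sequence.
    """

    values: pd.DataFrame
    cohorts: dict[str, str]
    sequences: pd.Series
    provenance: Provenance

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def cohort_samples(self, cohort: str) -> list[str]:
        return [s for s in self.sample_ids if self.cohorts[s] == cohort]

    def with_values(self, values: pd.DataFrame, normalization: str) -> "IntensityMatrix":
        return IntensityMatrix(
            values=values,
            cohorts=dict(self.cohorts),
            sequences=self.sequences,
            provenance=replace(self.provenance, normalization=normalization),
        )


def compute_intensity(
    f_l,
    b_l,
    b_m: float,
    mode: IntensityMode | str = IntensityMode.BACKGROUND_SCALE,
):
    """Per-spot intensity under the selected mode (vectorized over spots).

    In scale mode, local backgrounds are floored at
    max(1 RFU, 1e-6 * b_m) to keep the b_m/b_l ratio finite on
    zero-background spots; a warning reports how many spots were floored.
    """
    mode = IntensityMode(mode)
    f_l = np.asarray(f_l, dtype=float)
    b_l = np.asarray(b_l, dtype=float)
    if mode is IntensityMode.FOREGROUND:
        return f_l + 0.0
    if mode is IntensityMode.BACKGROUND_SUBTRACT:
        return f_l - b_l
    eps = np.maximum(1.0, 1e-6 * np.asarray(b_m, dtype=float))
    floored = b_l < eps
    if np.any(floored):
        warnings.warn(
            f"{int(np.sum(floored))} spot(s) with background < {eps:g} RFU floored "
            "in background-scale mode",
            stacklevel=2,
        )
        b_l = np.where(floored, eps, b_l)
    return f_l * b_m / b_l - b_m


def aggregate_replicates(values, method: str = "median") -> float:
    """Collapse replicate spot intensities of one peptide to one value."""
    if method != "median":
        raise ValueError(f"unsupported aggregation method {method!r}")
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("replicate group is empty")
    return float(np.median(arr))


def sample_peptide_values(
    sample: ArraySample,
    mode: IntensityMode | str,
    aggregate: bool = True,
    replicate_suffix: str = DEFAULT_REPLICATE_SUFFIX,
) -> pd.DataFrame:
    """Per-peptide intensities for one array.

    Returns a DataFrame indexed by peptide ID with columns ``sequence``,
    ``value``, ``n_rep`` and ``cv`` (coefficient of variation across
    replicates, for QC).  With ``aggregate=True`` replicate spots are
    grouped by peptide sequence and collapsed by median; the group's ID
    is its first spot's ID with the replicate suffix stripped.  With
    ``aggregate=False`` every spot is kept as its own row.
    """
    b_m = sample.median_background
    fg = np.array([s.foreground for s in sample.spots])
    bg = np.array([s.background for s in sample.spots])
    intensity = compute_intensity(fg, bg, b_m, mode)
    df = pd.DataFrame(
        {
            "spot_id": [s.spot_id for s in sample.spots],
            "sequence": [s.sequence for s in sample.spots],
            "value": intensity,
        }
    )
    if not aggregate:
        out = df.set_index("spot_id")[["sequence", "value"]]
        out["n_rep"] = 1
        out["cv"] = 0.0
        return out

    strip = re.compile(replicate_suffix) if replicate_suffix else None

    def _rep_id(spot_ids: pd.Series) -> str:
        first = spot_ids.iloc[0]
        return strip.sub("", first) if strip else first

    groups = df.groupby("sequence", sort=False)
    agg = pd.DataFrame(
        {
            "peptide_id": groups["spot_id"].apply(_rep_id),
            "value": groups["value"].median(),
            "n_rep": groups["value"].size(),
            "mean": groups["value"].mean(),
            "sd": groups["value"].std(ddof=1).fillna(0.0),
        }
    ).reset_index()
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(agg["mean"].abs() > 0, agg["sd"] / agg["mean"].abs(), np.nan)
    out = pd.DataFrame(
        {
            "sequence": agg["sequence"].to_numpy(),
            "value": agg["value"].to_numpy(),
            "n_rep": agg["n_rep"].to_numpy(),
            "cv": cv,
        },
        index=pd.Index(agg["peptide_id"], name="peptide_id"),
    )
    return out


def assemble_matrix(
    samples,
    mode: IntensityMode | str = IntensityMode.BACKGROUND_SCALE,
    aggregate: bool = True,
    replicate_suffix: str = DEFAULT_REPLICATE_SUFFIX,
) -> IntensityMatrix:
    """Build the peptide x sample matrix from parsed arrays.

    Requires at least one sample per cohort and an identical peptide set
    in every sample (a mismatch reports up to 20 offending keys).
    Peptide order follows the first sample; sample order is the control
    block (in upload order) followed by the treatment block.
    """
    samples = list(samples)
    control = [s for s in samples if s.cohort == "control"]
    treatment = [s for s in samples if s.cohort == "treatment"]
    if not control or not treatment:
        raise ArrayValidationError(
            f"need >=1 sample per cohort, got {len(control)} control / "
            f"{len(treatment)} treatment"
        )
    ordered = control + treatment
    per_sample = {
        s.sample_id: sample_peptide_values(s, mode, aggregate, replicate_suffix)
        for s in ordered
    }
    first = ordered[0]
    ref = per_sample[first.sample_id]
    ref_keys = set(ref.index)
    for s in ordered[1:]:
        keys = set(per_sample[s.sample_id].index)
        if keys != ref_keys:
            diff = sorted(keys.symmetric_difference(ref_keys))
            raise ArrayValidationError(
                f"peptide sets differ between {first.sample_id!r} and "
                f"{s.sample_id!r}; symmetric difference ({len(diff)} keys): {diff[:20]}"
            )
    values = pd.DataFrame(
        {s.sample_id: per_sample[s.sample_id]["value"].reindex(ref.index) for s in ordered}
    )
    values.index.name = "peptide_id"
    return IntensityMatrix(
        values=values,
        cohorts={s.sample_id: s.cohort for s in ordered},
        sequences=ref["sequence"].copy(),
        provenance=Provenance(
            intensity_mode=IntensityMode(mode).value, aggregated=aggregate
        ),
    )
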