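"""Synoptic and targeted visualizations.

Every plot is split into a *plot-data* structure (the test surface:
plain numbers, exportable as CSV/JSON) and a thin matplotlib renderer
that never alters values.  Synoptic plots (boxplot, mean-variance,
mean-median, heat map, swarm, dendrogram, PCA cluster plots) consume
the intensity matrix or the rank-cutoff subsets; targeted plots
(positional heat map, three-panel line graph, strip plot, epitope map)
consume only the synoptic results table plus a targeting file — never
the raw spot files — mirroring the two-stage workflow.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .arrayio import ArrayValidationError, SynopticTable, TargetingTable, validate_contiguous
from .preprocess import IntensityMatrix

FORMATS = ("png", "svg", "pdf")

CONTROL_COLOR = "red"
TREATMENT_COLOR = "white"

# deterministic SVG output (stable element ids, no timestamps)
matplotlib.rcParams["svg.hashsalt"] = "peparray"


# --- synoptic distribution summaries ---------------------------------------


@dataclass
class BoxplotStats:
    """Tukey box-and-whisker summary of one sample's peptide values."""

    sample_id: str
    cohort: str
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


@dataclass
class DistributionSummaries:
    boxplots: list[BoxplotStats]
    # per peptide within each cohort, over ALL peptides (no filtering)
    mean_variance: dict[str, pd.DataFrame]  # cohort -> columns mean, variance
    mean_median: dict[str, pd.DataFrame]  # cohort -> columns mean, median


def _tukey_box(values: np.ndarray) -> tuple[float, float, float, float, float, np.ndarray]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    whisker_low = float(inside.min()) if inside.size else float(q1)
    whisker_high = float(inside.max()) if inside.size else float(q3)
    outliers = values[(values < lo_fence) | (values > hi_fence)]
    return float(q1), float(med), float(q3), whisker_low, whisker_high, outliers


def build_distribution_summaries(matrix: IntensityMatrix) -> DistributionSummaries:
    """Boxplot stats per sample plus per-peptide mean-variance and
    mean-median pairs per cohort, over all peptides with no filtering."""
    boxplots = []
    for s in matrix.sample_ids:
        vals = matrix.values[s].to_numpy(dtype=float)
        q1, med, q3, wl, wh, out = _tukey_box(vals)
        boxplots.append(
            BoxplotStats(
                sample_id=s,
                cohort=matrix.cohorts[s],
                q1=q1,
                median=med,
                q3=q3,
                whisker_low=wl,
                whisker_high=wh,
                outliers=out,
            )
        )
    mean_variance = {}
    mean_median = {}
    for cohort in ("control", "treatment"):
        cols = matrix.cohort_samples(cohort)
        block = matrix.values[cols]
        mean = block.mean(axis=1)
        mean_variance[cohort] = pd.DataFrame(
            {"mean": mean, "variance": block.var(axis=1, ddof=1).fillna(0.0)}
        )
        mean_median[cohort] = pd.DataFrame({"mean": mean, "median": block.median(axis=1)})
    return DistributionSummaries(
        boxplots=boxplots, mean_variance=mean_variance, mean_median=mean_median
    )


# --- targeted plot data -----------------------------------------------------


def _targeted_rows(table: SynopticTable, targeting: TargetingTable) -> pd.DataFrame:
    """Synoptic rows for the targeted spot IDs, annotated with positions."""
    rows = []
    for rec in targeting:
        row = table.row_for(rec.spot_id)  # raises naming a missing ID
        rows.append(
            {
                "spot_id": rec.spot_id,
                "protein": rec.protein,
                "start": rec.start,
                "end": rec.end,
                **{s: row[s] for s in table.sample_ids},
                "delta_rfu": row["delta_rfu"],
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PositionalHeatmap:
    """Peptide x sample values, rows ordered N-terminus to C-terminus."""

    spot_ids: list[str]
    starts: list[int]
    sample_ids: list[str]
    cohorts: list[str]
    values: np.ndarray  # (n_peptides, n_samples)


def build_positional_heatmap(
    table: SynopticTable, targeting: TargetingTable
) -> PositionalHeatmap:
    validate_contiguous(targeting)
    df = _targeted_rows(table, targeting).sort_values(
        ["start", "spot_id"], kind="mergesort"
    )
    sample_ids = table.sample_ids
    cohorts = ["control"] * len(table.control_samples) + ["treatment"] * len(
        table.treatment_samples
    )
    return PositionalHeatmap(
        spot_ids=df["spot_id"].tolist(),
        starts=df["start"].astype(int).tolist(),
        sample_ids=sample_ids,
        cohorts=cohorts,
        values=df[sample_ids].to_numpy(dtype=float),
    )


@dataclass
class SubsetHeatmap:
    """Untargeted heat map variant: rows ordered by subset rank."""

    spot_ids: list[str]
    sample_ids: list[str]
    cohorts: list[str]
    values: np.ndarray


def build_subset_heatmap(table: SynopticTable, subset_ids) -> SubsetHeatmap:
    values = table.sample_values().loc[list(subset_ids)]
    cohorts = ["control"] * len(table.control_samples) + ["treatment"] * len(
        table.treatment_samples
    )
    return SubsetHeatmap(
        spot_ids=list(subset_ids),
        sample_ids=table.sample_ids,
        cohorts=cohorts,
        values=values.to_numpy(dtype=float),
    )


@dataclass
class BandProfile:
    """Three-panel line-graph data along protein positions.

    For each cohort, ``center`` is the mean intensity at each peptide
    position and the band edges are +/- 1 standard deviation (n-1).
    ``effect`` is the treatment center minus the control center.
    """

    positions: list[int]
    spot_ids: list[str]
    center: dict[str, np.ndarray]
    lower: dict[str, np.ndarray]
    upper: dict[str, np.ndarray]
    effect: np.ndarray


def build_band_profile(table: SynopticTable, targeting: TargetingTable) -> BandProfile:
    validate_contiguous(targeting)
    df = _targeted_rows(table, targeting).sort_values(
        ["start", "spot_id"], kind="mergesort"
    )
    center: dict[str, np.ndarray] = {}
    lower: dict[str, np.ndarray] = {}
    upper: dict[str, np.ndarray] = {}
    for cohort, cols in (
        ("control", table.control_samples),
        ("treatment", table.treatment_samples),
    ):
        block = df[cols].to_numpy(dtype=float)
        m = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1) if block.shape[1] > 1 else np.zeros(len(df))
        center[cohort] = m
        lower[cohort] = m - sd
        upper[cohort] = m + sd
    return BandProfile(
        positions=df["start"].astype(int).tolist(),
        spot_ids=df["spot_id"].tolist(),
        center=center,
        lower=lower,
        upper=upper,
        effect=center["treatment"] - center["control"],
    )


@dataclass
class StripData:
    """Dot data for strip/swarm plots with a fixed global sample order.

    The dot at position n within every strip comes from the same sample:
    control block (upload order) then treatment block.
    """

    peptides: list[str]
    sample_ids: list[str]
    cohorts: list[str]
    dots: dict[str, list[tuple[str, str, float]]]  # peptide -> (sample, cohort, value)


def build_strip_data(
    table: SynopticTable, targeting: TargetingTable | None = None, peptides=None
) -> StripData:
    """Strip-plot data for targeted records or an explicit peptide list.

    Targeting records may be non-contiguous but must come from a single
    protein; for synoptic swarm plots pass ``peptides`` (a subset
    selection) instead of a targeting table.
    """
    if (targeting is None) == (peptides is None):
        raise ValueError("pass exactly one of targeting or peptides")
    if targeting is not None:
        if len(targeting.proteins) > 1:
            raise ArrayValidationError(
                f"strip plot accepts one protein, got {targeting.proteins}"
            )
        ids = [rec.spot_id for rec in targeting]
    else:
        ids = list(peptides)
    sample_ids = table.sample_ids
    cohorts = ["control"] * len(table.control_samples) + ["treatment"] * len(
        table.treatment_samples
    )
    dots = {}
    for spot_id in ids:
        row = table.row_for(spot_id)
        dots[spot_id] = [
            (s, c, float(row[s])) for s, c in zip(sample_ids, cohorts)
        ]
    return StripData(peptides=ids, sample_ids=sample_ids, cohorts=cohorts, dots=dots)


@dataclass
class EpitopeMapData:
    """Peptide segments on the source-protein index sequence.

    Overlapping peptides are stacked into lanes (greedy first-fit in
    start order); each segment is colored by its delta RFU on a
    diverging scale symmetric about zero.
    """

    segments: list[tuple[str, int, int, int, float]]  # (spot_id, start, end, lane, delta)
    index_range: tuple[int, int]
    color_limit: float  # scale is [-color_limit, +color_limit]


def build_epitope_map(table: SynopticTable, targeting: TargetingTable) -> EpitopeMapData:
    validate_contiguous(targeting)
    df = _targeted_rows(table, targeting).sort_values(
        ["start", "spot_id"], kind="mergesort"
    )
    lane_ends: list[int] = []
    segments = []
    for r in df.itertuples():
        for lane, last_end in enumerate(lane_ends):
            if r.start > last_end:
                lane_ends[lane] = r.end
                break
        else:
            lane = len(lane_ends)
            lane_ends.append(r.end)
        segments.append((r.spot_id, int(r.start), int(r.end), lane, float(r.delta_rfu)))
    limit = float(df["delta_rfu"].abs().max()) if len(df) else 0.0
    return EpitopeMapData(
        segments=segments,
        index_range=(int(df["start"].min()), int(df["end"].max())),
        color_limit=limit,
    )


# --- exports and rendering --------------------------------------------------


def export_plot_data(data, path: str | Path) -> None:
    """Write any plot-data structure as JSON (arrays become lists)."""

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="list")
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"cannot serialize {type(o)}")

    payload = dataclasses.asdict(data) if dataclasses.is_dataclass(data) else data
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, default=_default, indent=1)


def _check_format(path: str | Path, fmt: str | None) -> str:
    fmt = fmt or Path(path).suffix.lstrip(".").lower()
    if fmt not in FORMATS:
        raise ValueError(f"unknown image format {fmt!r}; choose from {FORMATS}")
    return fmt


def _save(fig, path, fmt):
    fig.savefig(path, format=fmt, dpi=300, metadata={"Date": None} if fmt in ("svg", "pdf") else None)
    plt.close(fig)


def render(data, path: str | Path, fmt: str | None = None, seed: int = 0) -> Path:
    """Render a plot-data structure to PNG/SVG/PDF.

    Dispatches on the plot-data type; rendering reads values but never
    changes them.  Jitter (strip plots) is seeded, so identical
    plot-data and seed give identical files.
    """
    fmt = _check_format(path, fmt)
    path = Path(path)
    if isinstance(data, DistributionSummaries):
        fig = _render_boxplot(data)
    elif isinstance(data, (PositionalHeatmap, SubsetHeatmap)):
        fig = _render_heatmap(data)
    elif isinstance(data, BandProfile):
        fig = _render_band_profile(data)
    elif isinstance(data, StripData):
        fig = _render_strip(data, seed)
    elif isinstance(data, EpitopeMapData):
        fig = _render_epitope_map(data)
    else:
        raise ValueError(f"no renderer for {type(data).__name__}")
    _save(fig, path, fmt)
    return path


def _render_boxplot(data: DistributionSummaries):
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(data.boxplots)), 4))
    stats = [
        {
            "med": b.median,
            "q1": b.q1,
            "q3": b.q3,
            "whislo": b.whisker_low,
            "whishi": b.whisker_high,
            "fliers": b.outliers,
            "label": b.sample_id,
        }
        for b in data.boxplots
    ]
    artists = ax.bxp(stats, patch_artist=True)
    for patch, b in zip(artists["boxes"], data.boxplots):
        patch.set_facecolor(CONTROL_COLOR if b.cohort == "control" else TREATMENT_COLOR)
        patch.set_edgecolor("black")
    ax.set_ylabel("intensity")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    return fig


def _render_heatmap(data):
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(data.values, aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_xticks(range(len(data.sample_ids)))
    ax.set_xticklabels(data.sample_ids, rotation=90, fontsize=6)
    ax.set_yticks(range(len(data.spot_ids)))
    if isinstance(data, PositionalHeatmap):
        ax.set_yticklabels(
            [f"{p} ({s})" for p, s in zip(data.spot_ids, data.starts)], fontsize=6
        )
        ax.set_ylabel("peptide (protein position, N- to C-terminus)")
    else:
        ax.set_yticklabels(data.spot_ids, fontsize=6)
        ax.set_ylabel("peptide (subset rank)")
    fig.colorbar(im, ax=ax, label="intensity")
    fig.tight_layout()
    return fig


def _render_band_profile(data: BandProfile):
    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(7, 7))
    x = data.positions
    for ax, cohort, tint in (
        (axes[0], "control", "tab:red"),
        (axes[1], "treatment", "tab:blue"),
    ):
        ax.fill_between(x, data.lower[cohort], data.upper[cohort], color=tint, alpha=0.5)
        ax.plot(x, data.center[cohort], color="white", lw=2)
        ax.set_ylabel(f"{cohort}\nintensity")
    axes[2].plot(x, data.effect, color="black")
    axes[2].axhline(0.0, color="grey", lw=0.5)
    axes[2].set_ylabel("effect size\n(delta RFU)")
    axes[2].set_xlabel("peptide start position")
    fig.tight_layout()
    return fig


def _render_strip(data: StripData, seed: int):
    rng = np.random.default_rng(seed)
    fig, ax = plt.subplots(figsize=(max(4, 0.8 * len(data.peptides)), 4))
    for i, pep in enumerate(data.peptides):
        dots = data.dots[pep]
        # horizontal-only jitter; dot ORDER semantics live in the data
        x = i + rng.uniform(-0.25, 0.25, size=len(dots))
        y = [v for _, _, v in dots]
        colors = [CONTROL_COLOR if c == "control" else "tab:blue" for _, c, _ in dots]
        ax.scatter(x, y, c=colors, edgecolors="black", linewidths=0.4, s=25)
    ax.set_xticks(range(len(data.peptides)))
    ax.set_xticklabels(data.peptides, rotation=90, fontsize=7)
    ax.set_ylabel("intensity")
    fig.tight_layout()
    return fig


def _render_epitope_map(data: EpitopeMapData):
    fig, ax = plt.subplots(figsize=(7, 3))
    cmap = plt.get_cmap("coolwarm")
    limit = data.color_limit or 1.0
    n_lanes = 1 + max((seg[3] for seg in data.segments), default=0)
    for spot_id, start, end, lane, delta in data.segments:
        ax.barh(
            y=lane,
            width=end - start + 1,
            left=start,
            height=0.8,
            color=cmap(0.5 + 0.5 * delta / limit),
            edgecolor="black",
            linewidth=0.3,
        )
    ax.set_xlim(data.index_range[0] - 1, data.index_range[1] + 1)
    ax.set_ylim(-0.5, n_lanes - 0.5)
    ax.set_xlabel("protein position (index sequence)")
    ax.set_yticks([])
    sm = plt.cm.ScalarMappable(
        cmap=cmap, norm=plt.Normalize(vmin=-limit, vmax=limit)
    )
    fig.colorbar(sm, ax=ax, label="delta RFU")
    fig.tight_layout()
    return fig


def render_dendrogram(linkage_tree, sample_ids, path, fmt=None, cohorts=None):
    """Render a UPGMA dendrogram with samples on the y-axis."""
    from scipy.cluster.hierarchy import dendrogram

    fmt = _check_format(path, fmt)
    fig, ax = plt.subplots(figsize=(6, max(3, 0.3 * len(sample_ids))))
    dendrogram(linkage_tree, labels=sample_ids, orientation="right", ax=ax)
    if cohorts is not None:
        by_sample = dict(zip(sample_ids, cohorts))
        for tick in ax.get_yticklabels():
            tick.set_color(
                CONTROL_COLOR if by_sample.get(tick.get_text()) == "control" else "black"
            )
    ax.set_xlabel("Euclidean distance (average linkage)")
    fig.tight_layout()
    _save(fig, path, fmt)
    return Path(path)


def render_pca_clusters(coords, explained, labels, cohorts, path, fmt=None, color_by_cohort=True):
    """Scatter of samples in the first two PCA axes, colored by cluster;
    cohort identity optionally shown by marker shape."""
    fmt = _check_format(path, fmt)
    coords = np.asarray(coords)
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 4))
    markers = {"control": "o", "treatment": "s"}
    for lab in np.unique(labels):
        for cohort in ("control", "treatment"):
            mask = (labels == lab) & (np.asarray(cohorts) == cohort)
            if not mask.any():
                continue
            ax.scatter(
                coords[mask, 0],
                coords[mask, 1],
                c=f"C{lab}",
                marker=markers[cohort] if color_by_cohort else "o",
                edgecolors="black",
                linewidths=0.4,
                label=f"cluster {lab}" + (f", {cohort}" if color_by_cohort else ""),
            )
    ax.set_xlabel(f"PC1 ({100 * explained[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * explained[1]:.1f}%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    _save(fig, path, fmt)
    return Path(path)


def render_scatter_pairs(pairs: pd.DataFrame, xlab, ylab, path, fmt=None):
    """Generic scatter used for mean-variance and mean-median plots."""
    fmt = _check_format(path, fmt)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(pairs.iloc[:, 0], pairs.iloc[:, 1], s=6, alpha=0.5)
    ax.set_xlabel(xlab)
    ax.set_ylabel(ylab)
    fig.tight_layout()
    _save(fig, path, fmt)
    return Path(path)
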