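"""Reading and writing of immunoarray spot data and analysis tables.

Two on-disk input formats are supported: GenePix results files (GPR, the
tab-delimited ATF 1.0 container exported by microarray scanner software)
and a minimal 4-column CSV layout (ID, peptide sequence, foreground,
background).  One file holds one array, i.e. one serum sample.  A third
input, the *targeting file*, maps spot IDs to a source protein and to
1-based start/end positions within it, and drives the targeted
visualizations.  The one output format is the synoptic results CSV: one
row per peptide with per-sample intensities, cohort means/variances,
delta RFU, and raw/adjusted p-values.
"""

from __future__ import annotations

import csv
import io
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

COHORTS = ("control", "treatment")


class ArrayFormatError(ValueError):
    """The file does not conform to the expected layout."""


class ArrayValidationError(ValueError):
    """The file parsed but violates a content invariant."""


@dataclass(frozen=True)
class SpotRecord:
    """One printed spot: a peptide with its measured intensities (RFU)."""

    spot_id: str
    sequence: str
    foreground: float
    background: float
    flag: int = 0
    grid_pos: tuple[int, int, int] | None = None  # (block, row, column)

    def __post_init__(self) -> None:
        if not self.spot_id:
            raise ArrayValidationError("spot_id must be non-empty")
        for name in ("foreground", "background"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ArrayValidationError(
                    f"{name} must be finite and >= 0 for spot {self.spot_id!r}, got {v}"
                )


@dataclass
class ArraySample:
    """All spots of one array plus its cohort label.

    ``median_background`` is derived from the spots; it is the global
    background term of the background-scaling intensity correction.
    """

    sample_id: str
    cohort: str
    spots: list[SpotRecord]

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ArrayValidationError(
                f"cohort must be one of {COHORTS}, got {self.cohort!r}"
            )
        if not self.spots:
            raise ArrayValidationError(f"sample {self.sample_id!r} has no spots")

    @property
    def median_background(self) -> float:
        return float(median(s.background for s in self.spots))


@dataclass(frozen=True)
class TargetingRecord:
    """One targeted peptide: its source protein and 1-based inclusive span."""

    pathogen: str
    protein: str
    start: int
    end: int
    spot_id: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ArrayValidationError(
                f"invalid span [{self.start}, {self.end}] for spot {self.spot_id!r}"
            )


@dataclass
class TargetingTable:
    records: list[TargetingRecord]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def proteins(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.protein, None)
        return list(seen)


@dataclass(frozen=True)
class ColumnMapping:
    """Maps GPR column headers to spot fields.

    Defaults follow the GenePix 635 nm channel (the red laser used with
    Alexa Fluor 647 detection); override for other scanner setups.
    """

    id_col: str = "ID"
    seq_col: str = "Name"
    fg_col: str = "F635 Median"
    bg_col: str = "B635 Median"
    flag_col: str = "Flags"

    def __post_init__(self) -> None:
        names = [self.id_col, self.seq_col, self.fg_col, self.bg_col, self.flag_col]
        if len(set(names)) != len(names):
            raise ArrayValidationError(f"column names must be distinct: {names}")


DEFAULT_MAPPING = ColumnMapping()

_GRID_COLS = ("Block", "Row", "Column")


def _float_cell(raw: str, col: str, line_no: int) -> float:
    try:
        return float(raw)
    except ValueError:
        raise ArrayFormatError(
            f"non-numeric value {raw!r} in column {col!r} at line {line_no}"
        ) from None


def read_gpr(
    path: str | Path,
    mapping: ColumnMapping | None = None,
    exclude_flagged: bool = True,
    sample_id: str | None = None,
    cohort: str = "control",
) -> ArraySample:
    """Read one ATF 1.0 GenePix results file into an :class:`ArraySample`.

    Spots with a negative quality flag are dropped when ``exclude_flagged``
    is true (GenePix marks bad spots with flag -50/-75/-100); the dropped
    count is logged.
    """
    path = Path(path)
    mapping = mapping or DEFAULT_MAPPING
    with open(path, newline="", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.upper().startswith("ATF"):
            raise ArrayFormatError(f"{path}: not an ATF file (missing ATF version line)")
        counts = fh.readline().split()
        if len(counts) < 1:
            raise ArrayFormatError(f"{path}: malformed ATF header-count line")
        try:
            n_header = int(counts[0])
        except ValueError:
            raise ArrayFormatError(f"{path}: malformed ATF header-count line") from None
        for _ in range(n_header):
            fh.readline()
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ArrayFormatError(f"{path}: missing column header row") from None
        col_idx = {name: i for i, name in enumerate(header)}
        for col in (mapping.id_col, mapping.seq_col, mapping.fg_col, mapping.bg_col):
            if col not in col_idx:
                raise ArrayFormatError(f"{path}: required column {col!r} not found")
        has_flags = mapping.flag_col in col_idx
        has_grid = all(c in col_idx for c in _GRID_COLS)

        spots: list[SpotRecord] = []
        n_flagged = 0
        # line number within the file, for error messages
        line_no = 2 + n_header + 1
        for row in reader:
            line_no += 1
            if not row or all(not c.strip() for c in row):
                continue
            flag = int(float(row[col_idx[mapping.flag_col]])) if has_flags else 0
            if exclude_flagged and flag < 0:
                n_flagged += 1
                continue
            spot_id = row[col_idx[mapping.id_col]].strip()
            seq = row[col_idx[mapping.seq_col]].strip()
            grid = None
            if has_grid:
                grid = tuple(int(float(row[col_idx[c]])) for c in _GRID_COLS)
            spots.append(
                SpotRecord(
                    spot_id=spot_id,
                    sequence=seq or spot_id,
                    foreground=_float_cell(row[col_idx[mapping.fg_col]], mapping.fg_col, line_no),
                    background=_float_cell(row[col_idx[mapping.bg_col]], mapping.bg_col, line_no),
                    flag=flag,
                    grid_pos=grid,
                )
            )
    if n_flagged:
        logger.info("%s: excluded %d flagged spots", path.name, n_flagged)
    return ArraySample(sample_id=sample_id or path.stem, cohort=cohort, spots=spots)


def _looks_numeric(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def read_spot_csv(
    path: str | Path,
    sample_id: str | None = None,
    cohort: str = "control",
) -> ArraySample:
    """Read a 4-column spot CSV (ID, sequence, foreground, background).

    A header row is auto-detected: if the foreground/background cells of
    the first row are non-numeric the row is treated as a header.
    Duplicate spot IDs are rejected.
    """
    path = Path(path)
    spots: list[SpotRecord] = []
    seen: dict[str, int] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        for line_no, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 4:
                raise ArrayFormatError(
                    f"{path}: line {line_no} has {len(row)} columns, need >= 4 "
                    "(ID, sequence, foreground, background)"
                )
            if line_no == 1 and not (_looks_numeric(row[2]) and _looks_numeric(row[3])):
                continue  # header row
            spot_id = row[0].strip()
            seen[spot_id] = seen.get(spot_id, 0) + 1
            seq = row[1].strip()
            spots.append(
                SpotRecord(
                    spot_id=spot_id,
                    sequence=seq or spot_id,
                    foreground=_float_cell(row[2], "foreground", line_no),
                    background=_float_cell(row[3], "background", line_no),
                )
            )
    dupes = sorted(k for k, n in seen.items() if n > 1)
    if dupes:
        raise ArrayValidationError(f"{path}: duplicate spot IDs: {dupes[:20]}")
    return ArraySample(sample_id=sample_id or path.stem, cohort=cohort, spots=spots)


def read_targeting(path: str | Path, require_contiguous: bool = True) -> TargetingTable:
    """Read a targeting CSV (pathogen, protein, start, end, spot_id).

    When ``require_contiguous`` is true (positional heatmap, line graph,
    epitope map) the records, sorted by start, must tile a gap-free run
    of positions within a single protein: each start may be at most one
    past the previous record's end.  Strip plots pass
    ``require_contiguous=False`` and accept arbitrary peptide sets.
    """
    path = Path(path)
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = ["pathogen", "protein", "start", "end", "spot_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ArrayFormatError(f"{path}: missing targeting columns {missing}")
    records = [
        TargetingRecord(
            pathogen=str(r.pathogen),
            protein=str(r.protein),
            start=int(r.start),
            end=int(r.end),
            spot_id=str(r.spot_id),
        )
        for r in df.itertuples()
    ]
    table = TargetingTable(records)
    if require_contiguous:
        validate_contiguous(table)
    return table


def validate_contiguous(table: TargetingTable) -> None:
    """Check single-protein, gap-free coverage; raise naming any gap."""
    proteins = table.proteins
    if len(proteins) > 1:
        raise ArrayValidationError(
            f"contiguous targeting requires a single protein, got {proteins}"
        )
    recs = sorted(table.records, key=lambda r: r.start)
    covered_end = recs[0].end
    for r in recs[1:]:
        if r.start > covered_end + 1:
            raise ArrayValidationError(
                f"positional gap {covered_end + 1}..{r.start - 1} in targeting of "
                f"protein {r.protein!r}"
            )
        covered_end = max(covered_end, r.end)


# --- synoptic results table -------------------------------------------------

STAT_COLUMNS = [
    "control_mean",
    "control_var",
    "treatment_mean",
    "treatment_var",
    "delta_rfu",
    "p_raw",
    "p_adj",
]


@dataclass
class SynopticTable:
    """Per-peptide differential-reactivity results plus per-sample values.

    ``data`` has columns: spot_id, sequence, one column per sample id
    (control block first, then treatment, each in upload order), then
    the seven statistics columns.
    """

    data: pd.DataFrame
    control_samples: list[str]
    treatment_samples: list[str]

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.control_samples) + list(self.treatment_samples)

    def sample_values(self) -> pd.DataFrame:
        """Peptide x sample value block, indexed by spot_id."""
        return self.data.set_index("spot_id")[self.sample_ids]

    def row_for(self, spot_id: str) -> pd.Series:
        hit = self.data[self.data["spot_id"] == spot_id]
        if hit.empty:
            raise ArrayValidationError(f"spot ID {spot_id!r} not in synoptic table")
        return hit.iloc[0]


def write_synoptic_csv(table: SynopticTable, path: str | Path) -> None:
    """Write the synoptic results CSV.

    Column order: spot ID, peptide sequence, per-sample values (control
    then treatment, upload order), control mean/variance, treatment
    mean/variance, delta RFU, raw p, adjusted p.  Sample columns carry a
    ``control:``/``treatment:`` prefix so that the (stateless) targeted
    stage can recover cohort membership from this file alone.  Floats
    are written with 12 significant digits so a read-back round trip is
    lossless well past 1e-9 relative.
    """
    df = table.data
    if df.isna().any().any():
        raise ArrayValidationError("synoptic table has missing cells; cannot write")
    out = pd.DataFrame()
    out["spot_id"] = df["spot_id"]
    out["sequence"] = df["sequence"]
    for s in table.control_samples:
        out[f"control:{s}"] = df[s]
    for s in table.treatment_samples:
        out[f"treatment:{s}"] = df[s]
    for c in STAT_COLUMNS:
        out[c] = df[c]
    out.to_csv(path, index=False, float_format="%.12g")


def read_synoptic_csv(path: str | Path) -> SynopticTable:
    """Read back a synoptic results CSV written by :func:`write_synoptic_csv`."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ["spot_id", "sequence", *STAT_COLUMNS]:
        if col not in df.columns:
            raise ArrayFormatError(f"{path}: missing synoptic column {col!r}")
    control = [c[len("control:"):] for c in df.columns if c.startswith("control:")]
    treatment = [c[len("treatment:"):] for c in df.columns if c.startswith("treatment:")]
    if not control or not treatment:
        raise ArrayFormatError(f"{path}: no per-sample cohort columns found")
    df = df.rename(
        columns={f"control:{s}": s for s in control}
        | {f"treatment:{s}": s for s in treatment}
    )
    df["spot_id"] = df["spot_id"].astype(str)
    df["sequence"] = df["sequence"].astype(str)
    return SynopticTable(data=df, control_samples=control, treatment_samples=treatment)
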