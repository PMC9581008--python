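"""Synthetic immunoarray experiments with known ground truth.

The generator emulates the commercial tiling design used for epitope
mapping: a protein tiled by 15-mer peptides with 11-residue overlap,
printed in triplicate, measured in two cohorts.  Spot foreground is a
per-peptide baseline reactivity (log-normal across peptides) times
multiplicative log-normal noise, plus the local optical background and
an additive Gaussian noise floor; the local background varies smoothly
across the array grid (a scanner-gradient artifact), which is what the
background-scaling intensity mode corrects.  A chosen fraction of
peptides is differentially reactive: shifted upward in the treatment
cohort by a multiple of the per-peptide spot noise SD.  Optional
per-sample affine distortions (offset, scale) emulate the calibration
differences that variance-stabilizing normalization removes.

Each sample is written as a matched GPR/CSV pair so both parsers can be
exercised on identical content; a JSON manifest records every parameter
and the true differential peptide IDs.
"""

from __future__ import annotations

import json
import string
from dataclasses import asdict, dataclass, field
from math import ceil, sqrt
from pathlib import Path

import numpy as np

from .arrayio import ArraySample, ArrayValidationError, SpotRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimSpec:
    """Parameters of one simulated experiment.

    Defaults describe the reference conditions used throughout the test
    suite: 2,000 tiled 15-mer peptides (11-residue overlap over an
    8,011-residue protein), triplicate spots, 10 + 10 samples, 5% of
    peptides differential at 4x the spot noise SD, 1,000 RFU baseline
    signal with a 10% multiplicative and 100 RFU additive noise floor,
    and a 30% top-to-bottom background gradient.
    """

    seed: int = 0
    protein_length: int = 8011
    peptide_length: int = 15
    overlap: int = 11
    replicates: int = 3
    n_control: int = 10
    n_treatment: int = 10
    differential_fraction: float = 0.05
    effect_size: float = 4.0  # multiples of the per-peptide spot noise SD
    baseline_mean: float = 1000.0  # RFU
    noise_sd: float = 100.0  # additive RFU floor
    log_noise_sd: float = 0.1  # SD of multiplicative log-normal noise
    reactivity_sdlog: float = 0.5  # peptide-to-peptide baseline spread
    background_mean: float = 150.0  # RFU
    background_noise_sd: float = 15.0
    background_gradient: float = 0.3  # relative top-to-bottom bias amplitude
    sample_affine: list[tuple[float, float]] | None = None  # per-sample (offset, scale)

    def __post_init__(self) -> None:
        if not self.overlap < self.peptide_length:
            raise ValueError("overlap must be smaller than peptide_length")
        for name in ("replicates", "n_control", "n_treatment"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.differential_fraction <= 1.0:
            raise ValueError("differential_fraction must be in [0, 1]")


def tile_protein(length: int, peptide_length: int = 15, overlap: int = 11):
    """Tile a protein with overlapping windows; 1-based inclusive spans.

    Windows start every ``peptide_length - overlap`` residues; if the
    last regular window stops short of the C-terminus, one extra window
    ending exactly at ``length`` is appended so coverage is complete.
    """
    if peptide_length > length:
        raise ValueError(
            f"peptide_length {peptide_length} exceeds protein length {length}"
        )
    if not overlap < peptide_length:
        raise ValueError("overlap must be smaller than peptide_length")
    step = peptide_length - overlap
    windows = [
        (start, start + peptide_length - 1)
        for start in range(1, length - peptide_length + 2, step)
    ]
    if windows[-1][1] < length:
        windows.append((length - peptide_length + 1, length))
    return windows


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment."""

    protein: str
    windows: list[tuple[int, int]]
    peptide_ids: list[str]
    sequences: list[str]
    differential_ids: list[str]
    effect_shifts: dict[str, float]  # RFU shift applied in the treatment cohort


def _grid(n_spots: int):
    n_cols = ceil(sqrt(n_spots))
    n_rows = ceil(n_spots / n_cols)
    rows = np.arange(n_spots) // n_cols
    cols = np.arange(n_spots) % n_cols
    gpos = rows / max(n_rows - 1, 1)  # normalized top-to-bottom position
    return rows + 1, cols + 1, gpos


def simulate_samples(spec: SimSpec) -> tuple[list[ArraySample], SimTruth]:
    """Generate the arrays of one experiment in memory.

    Reproducible from the seed alone; see module docstring for the
    generative model.
    """
    rng = np.random.default_rng(spec.seed)
    protein = "".join(rng.choice(list(AMINO_ACIDS), size=spec.protein_length))
    windows = tile_protein(spec.protein_length, spec.peptide_length, spec.overlap)
    n_pep = len(windows)
    width = max(4, len(str(n_pep)))
    peptide_ids = [f"pep{i + 1:0{width}d}" for i in range(n_pep)]
    sequences = [protein[s - 1:e] for s, e in windows]

    reactivity = spec.baseline_mean * rng.lognormal(
        mean=0.0, sigma=spec.reactivity_sdlog, size=n_pep
    )
    spot_sd = np.sqrt((reactivity * spec.log_noise_sd) ** 2 + spec.noise_sd**2)
    n_diff = int(round(spec.differential_fraction * n_pep))
    diff_idx = np.sort(rng.choice(n_pep, size=n_diff, replace=False))
    shifts = np.zeros(n_pep)
    shifts[diff_idx] = spec.effect_size * spot_sd[diff_idx]

    n_samples = spec.n_control + spec.n_treatment
    affine = spec.sample_affine or [(0.0, 1.0)] * n_samples
    if len(affine) != n_samples:
        raise ValueError(
            f"sample_affine has {len(affine)} entries for {n_samples} samples"
        )

    # spots laid out replicate-block by replicate-block so replicates of a
    # peptide land in different grid rows (different background bias)
    n_spots = n_pep * spec.replicates
    rows, cols, gpos = _grid(n_spots)
    pep_of_spot = np.tile(np.arange(n_pep), spec.replicates)
    rep_of_spot = np.repeat(np.arange(1, spec.replicates + 1), n_pep)
    bias = 1.0 + spec.background_gradient * gpos

    samples: list[ArraySample] = []
    cohorts = ["control"] * spec.n_control + ["treatment"] * spec.n_treatment
    for i, cohort in enumerate(cohorts):
        a_i, b_i = affine[i]
        signal = reactivity[pep_of_spot].copy()
        if cohort == "treatment":
            signal = signal + shifts[pep_of_spot]
        eta = rng.normal(0.0, spec.log_noise_sd, size=n_spots)
        eps_f = rng.normal(0.0, spec.noise_sd, size=n_spots)
        eps_b = rng.normal(0.0, spec.background_noise_sd, size=n_spots)
        fg = a_i + b_i * (bias * (signal * np.exp(eta) + spec.background_mean) + eps_f)
        bg = bias * spec.background_mean + eps_b
        fg = np.clip(fg, 0.0, None)
        bg = np.clip(bg, 0.0, None)
        name = f"{cohort}_{i + 1 if cohort == 'control' else i + 1 - spec.n_control:02d}"
        spots = [
            SpotRecord(
                spot_id=f"{peptide_ids[pep_of_spot[k]]}.{rep_of_spot[k]}",
                sequence=sequences[pep_of_spot[k]],
                foreground=round(float(fg[k]), 4),
                background=round(float(bg[k]), 4),
                flag=0,
                grid_pos=(1, int(rows[k]), int(cols[k])),
            )
            for k in range(n_spots)
        ]
        samples.append(ArraySample(sample_id=name, cohort=cohort, spots=spots))

    truth = SimTruth(
        protein=protein,
        windows=windows,
        peptide_ids=peptide_ids,
        sequences=sequences,
        differential_ids=[peptide_ids[i] for i in diff_idx],
        effect_shifts={peptide_ids[i]: float(shifts[i]) for i in diff_idx},
    )
    return samples, truth


GPR_HEADER_RECORDS = [
    "Type=GenePix Results 3",
    "Wavelengths=635",
    "Creator=peparray simulator",
]
GPR_COLUMNS = ["ID", "Name", "Block", "Row", "Column", "F635 Median", "B635 Median", "Flags"]


def write_gpr(sample: ArraySample, path: str | Path) -> None:
    """Write one array as an ATF 1.0 GenePix results file."""
    lines = ["ATF\t1.0", f"{len(GPR_HEADER_RECORDS)}\t{len(GPR_COLUMNS)}"]
    lines += [f'"{rec}"' for rec in GPR_HEADER_RECORDS]
    lines.append("\t".join(f'"{c}"' for c in GPR_COLUMNS))
    for s in sample.spots:
        block, row, col = s.grid_pos or (1, 1, 1)
        lines.append(
            "\t".join(
                [
                    f'"{s.spot_id}"',
                    f'"{s.sequence}"',
                    str(block),
                    str(row),
                    str(col),
                    f"{s.foreground:.4f}",
                    f"{s.background:.4f}",
                    str(s.flag),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_spot_csv(sample: ArraySample, path: str | Path) -> None:
    """Write one array in the 4-column CSV layout."""
    lines = ["ID,Sequence,Foreground,Background"]
    for s in sample.spots:
        lines.append(f"{s.spot_id},{s.sequence},{s.foreground:.4f},{s.background:.4f}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def simulate_experiment(spec: SimSpec, out_dir: str | Path) -> dict:
    """Generate an experiment and write per-sample GPR + CSV files plus a
    ground-truth manifest (manifest.json).  Returns the manifest dict.

    Identical specs (same seed) produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples, truth = simulate_samples(spec)
    files = []
    for sample in samples:
        gpr = out_dir / f"{sample.sample_id}.gpr"
        csv_path = out_dir / f"{sample.sample_id}.csv"
        write_gpr(sample, gpr)
        write_spot_csv(sample, csv_path)
        files.append(
            {"sample_id": sample.sample_id, "cohort": sample.cohort,
             "gpr": gpr.name, "csv": csv_path.name}
        )
    manifest = {
        "spec": asdict(spec),
        "n_peptides": len(truth.peptide_ids),
        "files": files,
        "differential_ids": truth.differential_ids,
        "effect_shifts": truth.effect_shifts,
        "windows": truth.windows,
        "peptide_ids": truth.peptide_ids,
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def simulate_affine_matrix(
    n_peptides: int,
    offsets,
    scales,
    seed: int = 0,
    mu_low: float = 0.2,
    mu_high: float = 7.5,
    h_noise_sd: float = 0.1,
):
    """Draw a matrix directly from the arsinh-affine calibration model.

    Peptide j has a latent stabilized level mu_j (uniform on
    [mu_low, mu_high]); the observation in sample i is

        x_ij = a_i + b_i * sinh(mu_j + eta_ij),  eta ~ N(0, h_noise_sd)

    so arsinh((x - a_i)/b_i) has constant variance by construction and
    (a_i, b_i) are exactly the parameters the variance-stabilizing fit
    targets.  (A multiplicative-plus-additive noise model of the form
    a_i + b_i*mu*e^eta + eps identifies the per-sample scale only up to
    the noise-SD ratio, so it cannot serve as a recovery harness.)  No
    peptide is differential.  Returns an
    :class:`~peparray.preprocess.IntensityMatrix` with half the samples
    labeled per cohort.
    """
    import pandas as pd

    from .preprocess import IntensityMatrix, Provenance

    offsets = np.asarray(offsets, dtype=float)
    scales = np.asarray(scales, dtype=float)
    if offsets.shape != scales.shape:
        raise ValueError("offsets and scales must have equal length")
    m = offsets.size
    rng = np.random.default_rng(seed)
    mu = rng.uniform(mu_low, mu_high, size=n_peptides)
    eta = rng.normal(0.0, h_noise_sd, size=(n_peptides, m))
    X = offsets + scales * np.sinh(mu[:, None] + eta)
    peptide_ids = [f"pep{i + 1:04d}" for i in range(n_peptides)]
    sample_ids = [f"s{i + 1:02d}" for i in range(m)]
    cohorts = {
        s: ("control" if i < m // 2 else "treatment") for i, s in enumerate(sample_ids)
    }
    values = pd.DataFrame(X, index=peptide_ids, columns=sample_ids)
    sequences = pd.Series(["X" * 15] * n_peptides, index=peptide_ids)
    return IntensityMatrix(
        values=values,
        cohorts=cohorts,
        sequences=sequences,
        provenance=Provenance(intensity_mode="foreground", aggregated=True),
    )
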