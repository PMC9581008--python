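"""Cross-sample normalization of the peptide x sample intensity matrix.

Three schemes, matching the two standard assumptions about immunoarray
data plus an explicit opt-out:

* ``quantile`` — assumes all arrays share (approximately) the same
  reactivity distribution and forces them onto the common distribution
  given by averaged order statistics.
* ``vsn`` — assumes each array measures an affine transform of a common
  ground truth, with variance increasing with the mean.  Each sample i
  gets a calibration (a_i, b_i) and values are transformed by
  arsinh((x - a_i)/b_i), which stabilizes the variance (log-like for
  large x, linear near 0, defined for negative x).  The calibration is
  fitted by a least-trimmed profile maximum likelihood under the model
  h(x_ij) ~ N(mu_j, sigma^2); trimming makes the fit robust to the
  minority of differentially reactive peptides, which is why the fit
  assumes most peptides are NOT differential.
* ``none`` — identity, with provenance updated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .preprocess import IntensityMatrix

logger = logging.getLogger(__name__)


class VsnConvergenceError(RuntimeError):
    pass


def no_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Identity normalization; only provenance changes."""
    return matrix.with_values(matrix.values.copy(), normalization="none")


def quantile_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Force every sample onto the mean-order-statistic reference distribution.

    Each sample's sorted values are replaced by the row means of the
    column-sorted matrix, preserving within-sample rank order.  Tied
    input values receive the mean of the reference values at the ranks
    they jointly occupy, so the result is invariant to how a sort breaks
    ties.  With a single sample this is a warning no-op.
    """
    X = matrix.values.to_numpy(dtype=float)
    n, m = X.shape
    if m < 2:
        warnings.warn("quantile normalization needs >=2 samples; returning input")
        return matrix.with_values(matrix.values.copy(), normalization="quantile")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(m):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = reference
        # ties: average the reference values their ranks span
        assigned = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
        out[:, j] = assigned
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(values, normalization="quantile")


@dataclass
class VsnFit:
    """Fitted per-sample arsinh calibration."""

    sample_ids: list[str]
    offsets: np.ndarray  # a_i
    scales: np.ndarray  # b_i > 0
    converged: bool
    iterations: int
    n_retained: int  # peptides kept by the trimmed fit


def _vsn_nll_grad(theta: np.ndarray, X: np.ndarray):
    """Negative profile log-likelihood and gradient.

    X is peptides x samples; theta = [a_1..a_S, log b_1..log b_S].
    mu_j and sigma are profiled out analytically.
    """
    n, m = X.shape
    a = theta[:m]
    b = np.exp(theta[m:])
    d = X - a  # broadcasts over rows
    D = d * d + b * b
    g = 1.0 / np.sqrt(D)
    h = np.arcsinh(d / b)
    r = h - h.mean(axis=1, keepdims=True)
    rss = float(np.sum(r * r))
    N = n * m
    rss = max(rss, 1e-300)
    nll = 0.5 * N * np.log(rss / N) + 0.5 * np.sum(np.log(D))
    # dh/da = -g ; dh/db = -u*g with u = d/b
    coef = N / rss
    grad_a = -coef * np.sum(r * g, axis=0) - np.sum(d / D, axis=0)
    grad_b = -coef * np.sum(r * (d / b) * g, axis=0) + np.sum(b / D, axis=0)
    grad = np.concatenate([grad_a, grad_b * b])  # chain rule for log b
    return nll, grad


def vsn_normalize(
    matrix: IntensityMatrix,
    seed: int = 0,
    trim: float = 0.9,
    max_iter: int = 500,
    tol: float = 1e-9,
    lts_rounds: int = 3,
) -> tuple[IntensityMatrix, VsnFit]:
    """Fit and apply the variance-stabilizing arsinh calibration.

    ``trim`` is the fraction of peptides retained by the least-trimmed
    likelihood: after each fit round the peptides with the largest
    across-sample residual sums are dropped and the model refitted, for
    ``lts_rounds`` rounds or until the retained set stabilizes.  The
    result is deterministic given the input; ``seed`` is recorded for
    provenance symmetry with other stages.
    """
    X = matrix.values.to_numpy(dtype=float)
    n, m = X.shape
    if m < 2:
        raise ValueError("VSN needs >=2 samples")
    if not (0.0 < trim <= 1.0):
        raise ValueError(f"trim fraction must be in (0, 1], got {trim}")

    # moment-based starting point: offset near the low quantile, scale
    # from the spread, per sample
    a0 = np.quantile(X, 0.02, axis=0)
    spread = np.quantile(X, 0.75, axis=0) - np.quantile(X, 0.25, axis=0)
    b0 = np.maximum(spread / 1.349, 1e-3 * (np.abs(a0) + 1.0))
    theta = np.concatenate([a0, np.log(b0)])

    n_keep = max(int(round(trim * n)), m + 2)
    keep = np.arange(n)
    total_iter = 0
    res = None
    for _ in range(max(lts_rounds, 1)):
        res = minimize(
            _vsn_nll_grad,
            theta,
            args=(X[keep],),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
        )
        total_iter += int(res.nit)
        theta = res.x
        a = theta[:m]
        b = np.exp(theta[m:])
        h = np.arcsinh((X - a) / b)
        resid = h - h.mean(axis=1, keepdims=True)
        score = np.sum(resid * resid, axis=1)
        new_keep = np.sort(np.argsort(score, kind="mergesort")[:n_keep])
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep
    assert res is not None
    if res.status == 1:  # iteration limit
        raise VsnConvergenceError(
            f"VSN calibration did not converge within {total_iter} iterations; "
            "consider quantile normalization instead"
        )

    a = theta[:m]
    b = np.exp(theta[m:])
    transformed = np.arcsinh((X - a) / b)
    values = pd.DataFrame(
        transformed, index=matrix.values.index, columns=matrix.values.columns
    )
    fit = VsnFit(
        sample_ids=matrix.sample_ids,
        offsets=a,
        scales=b,
        converged=bool(res.success),
        iterations=total_iter,
        n_retained=int(len(keep)),
    )
    return matrix.with_values(values, normalization="vsn"), fit


def normalize(
    matrix: IntensityMatrix, method: str, seed: int = 0, **kwargs
) -> IntensityMatrix:
    """Dispatch by method name: none | quantile | vsn."""
    if method == "none":
        return no_normalize(matrix)
    if method == "quantile":
        return quantile_normalize(matrix)
    if method == "vsn":
        return vsn_normalize(matrix, seed=seed, **kwargs)[0]
    raise ValueError(f"unknown normalization method {method!r}")
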