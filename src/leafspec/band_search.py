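"""Exhaustive two-band VI regression search with cross-validation.

For every ordered band pair (λi, λj) inside a wavelength window, the VI is
computed per sample and leaf chlorophyll content is regressed on it by simple
OLS under k-fold cross-validation.  The per-pair mean validation R² forms a
contour landscape over the (λi, λj) plane; the optimal bands are reported as
the unit-weight image-moment centroid of the top-R² region,

    (Cx, Cy) = (M10 / M00, M01 / M00),

with the region's half extent per axis as a ± tolerance.

The whole ordered grid is evaluated in one vectorised pass: with fixed fold
assignment, per-fold OLS coefficients and held-out metrics for every pair
reduce to moment sums over samples, so the full 351x351 grid at n = 120 runs
in seconds.  CI = SR - 1 is an affine map of the predictor, and OLS, R², RMSE
and Pearson r are invariant under affine predictor maps, so SR and CI grids
agree cell-for-cell by construction — a structural check surfaced in the
reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cube import SpectralAxis
from .indices import VI_KINDS, PredictionModel

#: |r| bins for qualitative correlation strength; boundary values go to the
#: higher-strength bin.
_STRENGTH_EDGES = (0.10, 0.40, 0.70, 0.90)
_STRENGTH_NAMES = ("negligible", "weak", "moderate", "strong", "very strong")


@dataclass(frozen=True)
class RegressionFit:
    """Simple-regression coefficients and in-sample metrics."""

    slope: float
    intercept: float
    r2: float
    rmse: float
    r: float
    n: int


@dataclass(frozen=True)
class FoldMetrics:
    fold: int
    n_train: int
    n_val: int
    r2: float
    rmse: float


@dataclass(frozen=True)
class CVResult:
    """k-fold cross-validation summary (unweighted means over folds)."""

    mean_r2: float
    mean_rmse: float
    k: int
    seed: int
    fold_metrics: tuple[FoldMetrics, ...]
    pooled_r2: float | None = None
    pooled_rmse: float | None = None


@dataclass
class BandPairGrid:
    """CV metrics over every ordered band pair for one VI family.

    ``r2_grid[a, b]`` is the mean validation R² for λi = axis_i[a],
    λj = axis_j[b]; excluded (degenerate or non-finite) pairs are NaN with the
    reason recorded in ``excluded``/``n_nonfinite``.
    """

    vi: str
    axis_i: SpectralAxis
    axis_j: SpectralAxis
    r2_grid: np.ndarray
    rmse_grid: np.ndarray
    r_grid: np.ndarray
    excluded: np.ndarray
    n_nonfinite: np.ndarray
    k: int
    seed: int
    n_samples: int

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table (vi, lambda_i_nm, lambda_j_nm, metrics)."""
        li, lj = np.meshgrid(
            self.axis_i.wavelengths_nm, self.axis_j.wavelengths_nm, indexing="ij"
        )
        return pd.DataFrame(
            {
                "vi": self.vi,
                "lambda_i_nm": li.ravel(),
                "lambda_j_nm": lj.ravel(),
                "mean_r2": self.r2_grid.ravel(),
                "mean_rmse": self.rmse_grid.ravel(),
                "r": self.r_grid.ravel(),
                "n_excluded": self.n_nonfinite.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")
        return path

    def to_npz(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez_compressed(
            path,
            vi=self.vi,
            wavelengths_i_nm=self.axis_i.wavelengths_nm,
            wavelengths_j_nm=self.axis_j.wavelengths_nm,
            r2_grid=self.r2_grid,
            rmse_grid=self.rmse_grid,
            r_grid=self.r_grid,
            excluded=self.excluded,
            n_nonfinite=self.n_nonfinite,
            k=self.k,
            seed=self.seed,
            n_samples=self.n_samples,
        )
        return path


@dataclass(frozen=True)
class CentroidResult:
    """Moment centroid of the top-R² region of a band-pair grid."""

    cx_nm: float
    cy_nm: float
    m00: float
    m10: float
    m01: float
    region_cells: int
    level: float
    half_width_i_nm: float
    half_width_j_nm: float


# ---------------------------------------------------------------------------
# Simple regression and cross-validation


def ols_fit(x, y) -> RegressionFit:
    """Closed-form simple linear regression of y on x with Eq.-style metrics.

    R² = 1 - SSres/SStot, RMSE = sqrt(mean squared residual) in y-units, and r
    is the Pearson correlation.  Requires n ≥ 3 and non-degenerate variance in
    both variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples for a meaningful fit")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx <= 0:
        raise ZeroDivisionError("predictor has zero variance")
    if syy <= 0:
        raise ZeroDivisionError("response has zero variance; R^2 undefined")
    sxy = float(xc @ yc)
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = yc - slope * xc
    ss_res = float(resid @ resid)
    return RegressionFit(
        slope=float(slope),
        intercept=intercept,
        r2=1.0 - ss_res / syy,
        rmse=float(np.sqrt(ss_res / n)),
        r=sxy / np.sqrt(sxx * syy),
        n=n,
    )


def fold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Shuffled near-equal validation folds (sizes differ by at most one)."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    perm = np.random.default_rng(seed).permutation(n)
    return list(np.array_split(perm, k))


def _validation_metrics(y_val: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """Held-out R² (about the fold's own mean) and RMSE."""
    resid = y_val - y_pred
    ss_res = float(resid @ resid)
    dev = y_val - y_val.mean()
    ss_tot = float(dev @ dev)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return r2, float(np.sqrt(ss_res / y_val.size))


def kfold_cv(x, y, k: int = 10, seed: int = 0, pooled: bool = False) -> CVResult:
    """k-fold cross-validated simple regression of y on x.

    Samples are shuffled with ``seed`` and split into k near-equal validation
    folds.  Each fold's model is fitted on the remaining samples; validation
    R² uses the held-out fold's own mean.  The summary is the unweighted mean
    of per-fold metrics; ``pooled=True`` additionally reports metrics over the
    concatenated out-of-fold predictions.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    folds = fold_indices(x.size, k, seed)
    metrics: list[FoldMetrics] = []
    pooled_pred = np.empty_like(y)
    for f, val_idx in enumerate(folds):
        train = np.setdiff1d(np.arange(x.size), val_idx)
        fit = ols_fit(x[train], y[train])
        pred = fit.slope * x[val_idx] + fit.intercept
        pooled_pred[val_idx] = pred
        r2, rmse = _validation_metrics(y[val_idx], pred)
        metrics.append(
            FoldMetrics(fold=f, n_train=train.size, n_val=val_idx.size, r2=r2, rmse=rmse)
        )
    pooled_r2 = pooled_rmse = None
    if pooled:
        pooled_r2, pooled_rmse = _validation_metrics(y, pooled_pred)
    return CVResult(
        mean_r2=float(np.mean([m.r2 for m in metrics])),
        mean_rmse=float(np.mean([m.rmse for m in metrics])),
        k=k,
        seed=seed,
        fold_metrics=tuple(metrics),
        pooled_r2=pooled_r2,
        pooled_rmse=pooled_rmse,
    )


# ---------------------------------------------------------------------------
# Full-grid search


def _vi_tensor(spectra: np.ndarray, kind: str) -> np.ndarray:
    """VI values for all ordered band pairs: shape (n, bi, bj)."""
    ri = spectra[:, :, None]
    rj = spectra[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        if kind == "SR":
            return ri / rj
        if kind == "CI":
            return ri / rj - 1.0
        return (ri - rj) / (ri + rj)


def pair_search(
    spectra,
    axis: SpectralAxis,
    lcc,
    vi: str,
    window_nm: tuple[float, float] = (450.0, 800.0),
    k: int = 10,
    seed: int = 0,
) -> BandPairGrid:
    """Cross-validated regression of LCC on the VI at every ordered band pair.

    ``spectra`` is samples x bands reflectance; the fold assignment (from
    ``seed``) is identical for every pair, so grids for different VI families
    and re-runs are directly comparable and bit-reproducible.  Pairs with a
    non-finite VI for any sample, or with a degenerate (zero-variance)
    predictor in any training fold — e.g. the λi = λj diagonal, where all
    three families are constant — are excluded (NaN) with the offending-sample
    count recorded.
    """
    vi = vi.upper()
    if vi not in VI_KINDS:
        raise ValueError(f"unknown VI kind '{vi}'")
    spectra = np.asarray(spectra, dtype=float)
    y = np.asarray(lcc, dtype=float)
    if spectra.ndim != 2 or spectra.shape[0] != y.size:
        raise ValueError("spectra must be (n_samples, n_bands) matching lcc length")
    sel = axis.window(*window_nm)
    if sel.size < 2:
        raise ValueError("window contains fewer than two bands")
    sub_axis = axis.restrict(sel)
    sub = spectra[:, sel]
    n = y.size
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")

    V = _vi_tensor(sub, vi)  # (n, b, b)
    finite = np.isfinite(V)
    n_nonfinite = (~finite).sum(axis=0).astype(int)
    ok = n_nonfinite == 0
    V = np.where(finite, V, 0.0)

    # centre predictor and response once for numerical stability
    m = V.mean(axis=0)
    Vc = V - m[None, :, :]
    yc = y - y.mean()
    syy_full = float(yc @ yc)

    b = len(sub_axis)
    folds = fold_indices(n, k, seed)
    r2_sum = np.zeros((b, b))
    rmse_sum = np.zeros((b, b))
    degenerate = np.zeros((b, b), dtype=bool)

    for val_idx in folds:
        t = np.ones(n, dtype=bool)
        t[val_idx] = False
        yt, yv = yc[t], yc[val_idx]
        nt, nv = float(yt.size), float(yv.size)
        # training moments per pair
        sx = np.einsum("sij->ij", Vc[t])
        sxx = np.einsum("sij,sij->ij", Vc[t], Vc[t])
        sxy = np.einsum("s,sij->ij", yt, Vc[t])
        xbar = sx / nt
        ybar = yt.mean()
        sxx_c = sxx - nt * xbar**2
        sxy_c = sxy - nt * xbar * ybar
        degenerate |= sxx_c <= 0
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = sxy_c / sxx_c
        icept = ybar - slope * xbar
        # validation moments per pair
        sx_v = np.einsum("sij->ij", Vc[val_idx])
        sxx_v = np.einsum("sij,sij->ij", Vc[val_idx], Vc[val_idx])
        sxy_v = np.einsum("s,sij->ij", yv, Vc[val_idx])
        sy_v = yv.sum()
        syy_v = float(yv @ yv)
        ss_res = (
            syy_v
            + nv * icept**2
            + slope**2 * sxx_v
            - 2.0 * icept * sy_v
            - 2.0 * slope * sxy_v
            + 2.0 * icept * slope * sx_v
        )
        ss_res = np.maximum(ss_res, 0.0)
        ss_tot = syy_v - sy_v**2 / nv
        with np.errstate(divide="ignore", invalid="ignore"):
            r2_sum += 1.0 - ss_res / ss_tot
        rmse_sum += np.sqrt(ss_res / nv)

    # full-data Pearson r per pair
    sxx_full = np.einsum("sij,sij->ij", Vc, Vc)
    sxy_full = np.einsum("s,sij->ij", yc, Vc)
    degenerate |= sxx_full <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r_full = sxy_full / np.sqrt(sxx_full * syy_full)

    excluded = ~ok | degenerate
    r2 = np.where(excluded, np.nan, r2_sum / k)
    rmse = np.where(excluded, np.nan, rmse_sum / k)
    r_full = np.where(excluded, np.nan, r_full)
    # metrics that came out non-finite despite finite inputs are excluded too
    bad = ~(np.isfinite(r2) & np.isfinite(rmse) & np.isfinite(r_full)) & ~excluded
    excluded |= bad
    r2[bad] = rmse[bad] = r_full[bad] = np.nan

    return BandPairGrid(
        vi=vi,
        axis_i=sub_axis,
        axis_j=sub_axis,
        r2_grid=r2,
        rmse_grid=rmse,
        r_grid=r_full,
        excluded=excluded,
        n_nonfinite=n_nonfinite,
        k=k,
        seed=seed,
        n_samples=n,
    )


def top_region(grid: BandPairGrid, delta: float = 0.01) -> np.ndarray:
    """Boolean mask of the top-R² contour region.

    Candidate cells lie within ``delta`` of the grid maximum; the region is
    the 8-connected component of those cells that contains the maximum.  The
    connectivity restriction matters for ND, whose antisymmetry makes the
    mirrored cell (λj, λi) attain exactly the same R²: without it the region
    would straddle both mirrored blobs and the centroid would collapse onto
    the λi = λj diagonal.  Among cells tied at the maximum the seed with
    λi ≥ λj (the NIR-over-green orientation) is preferred.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    r2 = grid.r2_grid
    finite = np.isfinite(r2)
    if not finite.any():
        raise ValueError("all grid cells are excluded; nothing to select")
    top = np.nanmax(r2)
    candidates = finite & (r2 >= top - delta)
    peaks = np.argwhere(finite & (r2 >= top))
    seed = peaks[0]
    for ii, jj in peaks:
        if grid.axis_i.wavelengths_nm[ii] >= grid.axis_j.wavelengths_nm[jj]:
            seed = (ii, jj)
            break
    from scipy import ndimage

    labels, _ = ndimage.label(candidates, structure=np.ones((3, 3), dtype=int))
    return labels == labels[tuple(seed)]


def top_region_centroid(grid: BandPairGrid, delta: float = 0.01) -> CentroidResult:
    """Moment centroid of the top-R² contour region.

    Unit-weight image moments over the region's cell coordinates in nm give
    Cx = M10/M00 on the λi axis and Cy = M01/M00 on the λj axis; the region's
    half extent per axis is the reported ± tolerance.  See :func:`top_region`
    for how the region is selected.
    """
    region = top_region(grid, delta)
    top = np.nanmax(grid.r2_grid)
    ii, jj = np.nonzero(region)
    li = grid.axis_i.wavelengths_nm[ii]
    lj = grid.axis_j.wavelengths_nm[jj]
    m00 = float(ii.size)
    m10 = float(li.sum())
    m01 = float(lj.sum())
    return CentroidResult(
        cx_nm=m10 / m00,
        cy_nm=m01 / m00,
        m00=m00,
        m10=m10,
        m01=m01,
        region_cells=int(ii.size),
        level=float(top - delta),
        half_width_i_nm=float((li.max() - li.min()) / 2),
        half_width_j_nm=float((lj.max() - lj.min()) / 2),
    )


def strength_label(r: float) -> str:
    """Qualitative correlation strength from |r|.

    Bins: negligible [0, 0.10), weak [0.10, 0.40), moderate [0.40, 0.70),
    strong [0.70, 0.90), very strong [0.90, 1.00]; boundary values fall in the
    higher-strength bin.
    """
    if not np.isfinite(r) or abs(r) > 1:
        raise ValueError("r must lie in [-1, 1]")
    a = abs(r)
    idx = int(np.searchsorted(_STRENGTH_EDGES, a, side="right"))
    return _STRENGTH_NAMES[idx]


def fit_final_model(
    spectra,
    axis: SpectralAxis,
    lcc,
    vi: str,
    centroid: CentroidResult,
) -> tuple[PredictionModel, RegressionFit]:
    """Full-data OLS of LCC on the VI at the centroid's nearest band centres."""
    spectra = np.asarray(spectra, dtype=float)
    i = axis.nearest(centroid.cx_nm)
    j = axis.nearest(centroid.cy_nm)
    from .indices import compute_vi

    x = compute_vi(spectra[:, i], spectra[:, j], vi)
    fit = ols_fit(x, np.asarray(lcc, dtype=float))
    model = PredictionModel(
        vi=vi.upper(),
        lambda_i_nm=float(axis.wavelengths_nm[i]),
        lambda_j_nm=float(axis.wavelengths_nm[j]),
        slope=fit.slope,
        intercept=fit.intercept,
        provenance={
            "centroid_cx_nm": centroid.cx_nm,
            "centroid_cy_nm": centroid.cy_nm,
            "half_width_i_nm": centroid.half_width_i_nm,
            "half_width_j_nm": centroid.half_width_j_nm,
            "n": fit.n,
        },
    )
    return model, fit
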