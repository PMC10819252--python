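"""End-to-end orchestration: spectra + chemistry → band search → model → maps.

``run_analysis`` joins per-sample mean spectra with the chemistry table by
explicit sample id, runs the exhaustive band-pair search for each requested VI
family, selects optimal bands by contour centroid, fits the final two-band
model and cross-validates it, and writes grids, models and a deterministic
JSON report (timestamps live only in the manifest, so re-runs are
byte-identical).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from . import __version__
from .band_search import (
    BandPairGrid,
    CentroidResult,
    CVResult,
    RegressionFit,
    fit_final_model,
    kfold_cv,
    pair_search,
    strength_label,
    top_region_centroid,
)
from .chlorophyll import read_chlorophyll_table
from .cube import read_cube, read_spectra_csv, segment_leaf
from .indices import PredictionModel, compute_vi, lcc_map_to_csv, vi_map, write_lcc_map

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and knobs of one analysis run."""

    spectra_csv: str
    chemistry_csv: str
    outdir: str
    window_nm: tuple[float, float] = (450.0, 800.0)
    vis: tuple[str, ...] = ("ND", "SR", "CI")
    k: int = 10
    seed: int = 0
    delta: float = 0.01
    render_contours: bool = False

    def validate(self) -> None:
        lo, hi = self.window_nm
        if hi <= lo:
            raise ValueError(f"invalid wavelength window ({lo}, {hi})")
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        for p in (self.spectra_csv, self.chemistry_csv):
            if not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Read a flat ``key = value`` config file; keyword overrides win."""
        values: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, raw = line.partition("=")
            values[key.strip()] = raw.strip()
        kwargs: dict = {}
        for f in dataclasses.fields(cls):
            if f.name not in values:
                continue
            raw = values[f.name]
            if f.name == "window_nm":
                lo, hi = (float(t) for t in raw.split(","))
                kwargs[f.name] = (lo, hi)
            elif f.name == "vis":
                kwargs[f.name] = tuple(t.strip().upper() for t in raw.split(","))
            elif f.name in ("k", "seed"):
                kwargs[f.name] = int(raw)
            elif f.name == "delta":
                kwargs[f.name] = float(raw)
            elif f.name == "render_contours":
                kwargs[f.name] = raw.lower() in ("1", "true", "yes")
            else:
                kwargs[f.name] = raw
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class VIResult:
    """Per-VI-family results of one run."""

    vi: str
    grid: BandPairGrid
    centroid: CentroidResult
    model: PredictionModel
    fit: RegressionFit
    cv: CVResult
    strength: str


@dataclass
class RunReport:
    """All results of one analysis run plus reproducibility metadata."""

    per_vi: dict[str, VIResult]
    n_samples: int
    rejected_samples: dict[str, str]
    seed: int
    k: int
    window_nm: tuple[float, float]
    delta: float

    def to_dict(self) -> dict:
        out = {
            "software": {"package": "leafspec", "version": __version__},
            "seed": self.seed,
            "k": self.k,
            "window_nm": list(self.window_nm),
            "delta": self.delta,
            "n_samples": self.n_samples,
            "rejected_samples": self.rejected_samples,
            "results": {},
        }
        for vi, res in self.per_vi.items():
            out["results"][vi] = {
                "optimal_lambda_i_nm": res.centroid.cx_nm,
                "optimal_lambda_i_pm_nm": res.centroid.half_width_i_nm,
                "optimal_lambda_j_nm": res.centroid.cy_nm,
                "optimal_lambda_j_pm_nm": res.centroid.half_width_j_nm,
                "region_cells": res.centroid.region_cells,
                "cv_mean_r2": res.cv.mean_r2,
                "cv_mean_rmse_ug_cm2": res.cv.mean_rmse,
                "insample_r2": res.fit.r2,
                "insample_rmse_ug_cm2": res.fit.rmse,
                "pearson_r": res.fit.r,
                "strength": res.strength,
                "model_slope": res.model.slope,
                "model_intercept": res.model.intercept,
                "model_bands_nm": [res.model.lambda_i_nm, res.model.lambda_j_nm],
            }
        return out


def _join_samples(config: RunConfig):
    wide, axis = read_spectra_csv(config.spectra_csv)
    chem = read_chlorophyll_table(config.chemistry_csv).set_index("sample_id")
    spec_ids = set(map(str, wide.index))
    chem_ids = set(chem.index)
    missing_chem = sorted(spec_ids - chem_ids)
    missing_spec = sorted(chem_ids - spec_ids)
    for sid in missing_chem:
        logger.warning("sample %s has spectra but no chemistry record", sid)
    for sid in missing_spec:
        logger.warning("sample %s has chemistry but no spectra", sid)
    common = sorted(spec_ids & chem_ids)
    if not common:
        raise ValueError(
            "no sample ids shared between spectra and chemistry tables; "
            f"spectra-only: {missing_chem[:5]}, chemistry-only: {missing_spec[:5]}"
        )
    rejected = {sid: "no matching record" for sid in missing_chem + missing_spec}
    wide = wide.loc[common]
    chem = chem.loc[common]

    lo, hi = config.window_nm
    if lo < axis.wavelengths_nm[0] or hi > axis.wavelengths_nm[-1]:
        raise ValueError(
            f"window ({lo}, {hi}) nm outside the data axis "
            f"[{axis.wavelengths_nm[0]}, {axis.wavelengths_nm[-1]}] nm"
        )
    sel = axis.window(lo, hi)
    in_window = wide.to_numpy(dtype=float)[:, sel]
    good = np.all(np.isfinite(in_window), axis=1)
    for sid, ok in zip(common, good):
        if not ok:
            rejected[sid] = "non-finite reflectance inside the search window"
            logger.warning("rejecting sample %s: invalid band in window", sid)
    ids = [sid for sid, ok in zip(common, good) if ok]
    spectra = wide.to_numpy(dtype=float)[good]
    lcc = chem["lcc_ug_cm2"].to_numpy(dtype=float)[good]
    return ids, spectra, axis, lcc, rejected


def _render_contour(grid: BandPairGrid, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    li = grid.axis_i.wavelengths_nm
    lj = grid.axis_j.wavelengths_nm
    cs = ax.contourf(li, lj, grid.r2_grid.T, levels=20, cmap="viridis")
    fig.colorbar(cs, ax=ax, label="mean validation $R^2$")
    ax.set_xlabel(r"$\lambda_i$ (nm)")
    ax.set_ylabel(r"$\lambda_j$ (nm)")
    ax.set_title(grid.vi)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_analysis(config: RunConfig) -> RunReport:
    """Execute the full band-search chain and write all outputs."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("leafspec")
    root.addHandler(handler)
    try:
        ids, spectra, axis, lcc, rejected = _join_samples(config)
        n = len(ids)
        logger.info("joined %d samples (%d rejected)", n, len(rejected))
        if n < config.k:
            raise ValueError(f"only {n} joined samples; need at least k={config.k}")
        per_vi: dict[str, VIResult] = {}
        for vi in config.vis:
            grid = pair_search(
                spectra, axis, lcc, vi,
                window_nm=config.window_nm, k=config.k, seed=config.seed,
            )
            n_excl = int(grid.excluded.sum())
            logger.info("%s grid: %d cells excluded of %d", vi, n_excl,
                        grid.excluded.size)
            centroid = top_region_centroid(grid, delta=config.delta)
            model, fit = fit_final_model(spectra, axis, lcc, vi, centroid)
            i = axis.nearest(model.lambda_i_nm)
            j = axis.nearest(model.lambda_j_nm)
            x = compute_vi(spectra[:, i], spectra[:, j], vi)
            cv = kfold_cv(x, lcc, k=config.k, seed=config.seed)
            per_vi[vi.upper()] = VIResult(
                vi=vi.upper(),
                grid=grid,
                centroid=centroid,
                model=model,
                fit=fit,
                cv=cv,
                strength=strength_label(fit.r),
            )
            grid.to_csv(outdir / f"grid_{vi.lower()}.csv")
            grid.to_npz(outdir / f"grid_{vi.lower()}.npz")
            model.to_json(outdir / f"model_{vi.lower()}.json")
            (outdir / f"centroid_{vi.lower()}.json").write_text(
                json.dumps(dataclasses.asdict(centroid), indent=2, sort_keys=True)
                + "\n"
            )
            if config.render_contours:
                _render_contour(grid, outdir / f"contour_{vi.lower()}.png")
        report = RunReport(
            per_vi=per_vi,
            n_samples=n,
            rejected_samples=rejected,
            seed=config.seed,
            k=config.k,
            window_nm=config.window_nm,
            delta=config.delta,
        )
        (outdir / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        manifest = {
            "created_utc": datetime.now(timezone.utc).isoformat(),
            "inputs": {
                "spectra_csv": str(config.spectra_csv),
                "chemistry_csv": str(config.chemistry_csv),
            },
            "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
            "package": f"leafspec {__version__}",
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        return report
    finally:
        root.removeHandler(handler)
        handler.close()


def predict_on_cube(
    cube_path: str | Path,
    model_path: str | Path,
    out_path: str | Path,
    threshold: float = 0.3,
    min_pixels: int = 10,
) -> dict:
    """Segment a cube, apply a two-band model per pixel, write the LCC map.

    Writes ``<out>.tif`` (float32, NaN background), ``<out>.csv`` (row, col,
    lcc) and ``<out>_summary.json``; returns the summary dict.
    """
    cube = read_cube(cube_path)
    model = PredictionModel.from_json(model_path)
    for lam, name in ((model.lambda_i_nm, "lambda_i"), (model.lambda_j_nm, "lambda_j")):
        wl = cube.axis.wavelengths_nm
        if not (wl[0] <= lam <= wl[-1]):
            raise ValueError(
                f"model band {name}={lam} nm outside cube axis "
                f"[{wl[0]}, {wl[-1]}] nm"
            )
    mask = segment_leaf(cube, threshold=threshold, min_pixels=min_pixels)
    lcc_map = vi_map(cube, mask, model)
    out_path = Path(out_path)
    base = out_path.with_suffix("") if out_path.suffix else out_path
    write_lcc_map(lcc_map, base.with_suffix(".tif"))
    lcc_map_to_csv(lcc_map, base.with_suffix(".csv"))
    leaf_vals = lcc_map[np.isfinite(lcc_map)]
    summary = {
        "n_leaf_pixels": int(leaf_vals.size),
        "n_samples": int(mask.sample_ids.size),
        "mean_lcc_ug_cm2": float(leaf_vals.mean()),
        "sd_lcc_ug_cm2": float(leaf_vals.std()),
        "model": {
            "vi": model.vi,
            "lambda_i_nm": model.lambda_i_nm,
            "lambda_j_nm": model.lambda_j_nm,
            "slope": model.slope,
            "intercept": model.intercept,
        },
    }
    Path(str(base) + "_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
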