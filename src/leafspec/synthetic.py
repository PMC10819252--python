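"""Synthetic leaf reflectance data with known ground truth.

The generator emulates the statistical structure the band-search analysis
assumes: ~120 leaf samples whose chlorophyll content spans 4–23 µg·cm⁻², with
reflectance spectra showing the four qualitative features of healthy green
vegetation — low blue and red reflectance, a green peak between 500 and
600 nm, a steep red edge near 700 nm, and a NIR plateau.

The spectral model is Beer–Lambert-style multiplicative absorption on a
logistic red-edge baseline:

    R(λ) = B(λ) · exp(-ε(λ) · LCC / ρ) + noise
    B(λ) = base + plateau · logistic((λ - red_edge_center) / red_edge_width)
    ε(λ) = Σ_k s_k · exp(-(λ - c_k)² / (2 w_k²))

with Gaussian absorption wells at the blue (450 nm) and red (670 nm)
chlorophyll bands and ρ a fixed LCC scale choosing the reflectance dynamic
range.  Every dataset ships a truth block: the generator config, the
most-informative band pair (the argmax of the noise-attenuated population R²
landscape, computed by brute force from the noiseless spectra), and the
planted VI → LCC law at that pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .chlorophyll import absorbance_from_lcc
from .cube import HyperCube, LeafMask, SpectralAxis

#: LCC scale ρ (µg·cm⁻²) of the Beer–Lambert exponent.  With the default well
#: strengths this makes the red well saturate over the 4–23 µg·cm⁻² range and
#: keeps the green peak (not the red-edge shoulder) the visible maximum, the
#: regime leaf spectra show.
LCC_SCALE_UG_CM2 = 2.4


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic leaf-reflectance generator.

    Defaults mirror the study conditions the analysis targets: 120 samples,
    LCC uniform over 4–23 µg·cm⁻², a 450–800 nm axis at 1 nm (351 bands), and
    additive reflectance noise of 0.005 (about 1% of the NIR plateau).
    """

    n_samples: int = 120
    lcc_range: tuple[float, float] = (4.0, 23.0)
    axis_start_nm: float = 450.0
    axis_stop_nm: float = 800.0
    n_bands: int = 351
    noise_sd: float = 0.005
    absorption_centers_nm: tuple[float, ...] = (450.0, 670.0)
    absorption_widths_nm: tuple[float, ...] = (40.0, 30.0)
    absorption_strengths: tuple[float, ...] = (1.0, 0.8)
    red_edge_center_nm: float = 710.0
    red_edge_width_nm: float = 12.0
    nir_plateau: float = 0.5
    base_reflectance: float = 0.08
    absorbance_ratio: float = 0.4
    absorbance_noise: float = 0.01
    dose_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError("need at least 10 samples")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if not (400.0 <= self.axis_start_nm < self.axis_stop_nm <= 900.0):
            raise ValueError("axis must lie within 400-900 nm")
        if not (
            len(self.absorption_centers_nm)
            == len(self.absorption_widths_nm)
            == len(self.absorption_strengths)
        ):
            raise ValueError("absorption centres/widths/strengths must align")

    @property
    def axis(self) -> SpectralAxis:
        return SpectralAxis(
            np.linspace(self.axis_start_nm, self.axis_stop_nm, self.n_bands)
        )


@dataclass
class SyntheticDataset:
    """Spectra + chemistry + ground truth for one generated leaf set."""

    spectra: np.ndarray  # (n_samples, n_bands)
    axis: SpectralAxis
    lcc: np.ndarray
    a647: np.ndarray
    a664: np.ndarray
    sample_ids: list[str]
    truth: dict
    config: GeneratorConfig

    def spectra_frame(self) -> pd.DataFrame:
        frames = []
        for sid, spec in zip(self.sample_ids, self.spectra):
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": sid,
                        "wavelength_nm": self.axis.wavelengths_nm,
                        "mean_reflectance": spec,
                        "sd_reflectance": self.config.noise_sd,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def chemistry_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "a647": self.a647,
                "a664": self.a664,
                "lcc_ug_cm2": self.lcc,
            }
        )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write spectra.csv, chemistry.csv and truth.json under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "spectra": outdir / "spectra.csv",
            "chemistry": outdir / "chemistry.csv",
            "truth": outdir / "truth.json",
        }
        self.spectra_frame().to_csv(paths["spectra"], index=False, float_format="%.10g")
        self.chemistry_frame().to_csv(
            paths["chemistry"], index=False, float_format="%.10g"
        )
        doc = {"config": asdict(self.config), "truth": self.truth}
        paths["truth"].write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
        return paths


# ---------------------------------------------------------------------------
# Spectral model


def _baseline(wl: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    return config.base_reflectance + config.nir_plateau * expit(
        (wl - config.red_edge_center_nm) / config.red_edge_width_nm
    )


def _extinction(wl: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    eps = np.zeros_like(wl)
    for c, w, s in zip(
        config.absorption_centers_nm,
        config.absorption_widths_nm,
        config.absorption_strengths,
    ):
        eps += s * np.exp(-((wl - c) ** 2) / (2 * w**2))
    return eps


def generate_spectrum(
    lcc: float,
    config: GeneratorConfig = GeneratorConfig(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One reflectance spectrum for a leaf of the given chlorophyll content.

    Noiseless when ``rng`` is None; otherwise additive Gaussian noise of sd
    ``config.noise_sd`` is applied and the result clamped at zero (matching
    the reflectance-calibration convention).
    """
    if lcc < 0:
        raise ValueError("LCC must be non-negative")
    wl = config.axis.wavelengths_nm
    refl = _baseline(wl, config) * np.exp(-_extinction(wl, config) * lcc / LCC_SCALE_UG_CM2)
    if rng is not None and config.noise_sd > 0:
        refl = np.maximum(refl + rng.normal(0.0, config.noise_sd, size=refl.shape), 0.0)
    return refl


def _noiseless_matrix(lcc: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    wl = config.axis.wavelengths_nm
    return _baseline(wl, config)[None, :] * np.exp(
        -np.outer(lcc, _extinction(wl, config)) / LCC_SCALE_UG_CM2
    )


def _attenuated_r2_landscape(
    spectra0: np.ndarray, lcc: np.ndarray, kind: str, noise_sd: float
) -> np.ndarray:
    """Population R² of the noisy VI against LCC, from noiseless spectra.

    For each ordered pair this is cov(v, y)² / ((var(v) + E[var_noise]) var(y))
    where v is the noiseless VI and the per-sample VI noise variance comes
    from first-order (delta-method) propagation of the reflectance noise.
    When ``noise_sd`` is zero this reduces to the plain in-sample R² of the
    noiseless landscape.
    """
    ri = spectra0[:, :, None]
    rj = spectra0[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        if kind in ("SR", "CI"):
            v = ri / rj
            dvi = 1.0 / rj
            dvj = -ri / rj**2
        else:
            s = ri + rj
            v = (ri - rj) / s
            dvi = 2.0 * rj / s**2
            dvj = -2.0 * ri / s**2
    n = spectra0.shape[0]
    y = lcc - lcc.mean()
    var_y = float(y @ y) / n
    vbar = v.mean(axis=0)
    vc = v - vbar[None, :, :]
    var_v = np.einsum("sij,sij->ij", vc, vc) / n
    cov = np.einsum("s,sij->ij", y, vc) / n
    nvar = (dvi**2 + dvj**2).mean(axis=0) * noise_sd**2
    with np.errstate(divide="ignore", invalid="ignore"):
        score = cov**2 / ((var_v + nvar) * var_y)
    return score


def _truth_pair(
    spectra0: np.ndarray, lcc: np.ndarray, config: GeneratorConfig, kind: str
) -> dict:
    wl = config.axis.wavelengths_nm
    score = _attenuated_r2_landscape(spectra0, lcc, kind, config.noise_sd)
    score = np.where(np.isfinite(score), score, -np.inf)
    np.fill_diagonal(score, -np.inf)  # degenerate constant predictor
    flat = int(np.argmax(score))
    i, j = np.unravel_index(flat, score.shape)
    if kind == "ND" and wl[i] < wl[j]:
        # ND antisymmetry: (j, i) attains exactly the same score; report the
        # NIR-over-green orientation, matching the search's tie preference
        i, j = j, i
    # population-level value of the selection functional the analysis applies:
    # the top-region moment centroid of the landscape (the estimand that band
    # selection targets; the argmax alone is ill-determined along flat ridges)
    from .band_search import BandPairGrid, top_region_centroid

    nan = np.full_like(score, np.nan)
    pop_grid = BandPairGrid(
        vi=kind, axis_i=config.axis, axis_j=config.axis,
        r2_grid=np.where(np.isfinite(score), score, np.nan),
        rmse_grid=nan, r_grid=nan,
        excluded=~np.isfinite(score),
        n_nonfinite=np.zeros_like(score, dtype=int),
        k=0, seed=config.seed, n_samples=lcc.size,
    )
    pop_centroid = top_region_centroid(pop_grid, delta=0.01)
    # planted law: full-data noiseless OLS at the truth pair
    if kind in ("SR", "CI"):
        v = spectra0[:, i] / spectra0[:, j]
        if kind == "CI":
            v = v - 1.0
    else:
        v = (spectra0[:, i] - spectra0[:, j]) / (spectra0[:, i] + spectra0[:, j])
    vc = v - v.mean()
    yc = lcc - lcc.mean()
    slope = float((vc @ yc) / (vc @ vc))
    intercept = float(lcc.mean() - slope * v.mean())
    return {
        "lambda_i_nm": float(wl[i]),
        "lambda_j_nm": float(wl[j]),
        "score": float(score[i, j]),
        "slope": slope,
        "intercept": intercept,
        "centroid_i_nm": pop_centroid.cx_nm,
        "centroid_j_nm": pop_centroid.cy_nm,
        "centroid_half_width_i_nm": pop_centroid.half_width_i_nm,
        "centroid_half_width_j_nm": pop_centroid.half_width_j_nm,
    }


def _draw_lcc(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.lcc_range
    if not config.dose_mode:
        return rng.uniform(lo, hi, size=config.n_samples)
    # five-level fertiliser-dose design: equal groups around evenly spaced means
    span = hi - lo
    levels = np.linspace(lo + 0.1 * span, hi - 0.1 * span, 5)
    means = levels[np.arange(config.n_samples) % 5]
    return np.clip(rng.normal(means, 0.08 * span), lo, hi)


def generate_dataset(config: GeneratorConfig = GeneratorConfig()) -> SyntheticDataset:
    """Generate a full seeded dataset: spectra, chemistry and truth block."""
    rng = np.random.default_rng(config.seed)
    lcc = _draw_lcc(config, rng)
    spectra0 = _noiseless_matrix(lcc, config)
    noisy = spectra0.copy()
    if config.noise_sd > 0:
        noisy = np.maximum(noisy + rng.normal(0.0, config.noise_sd, noisy.shape), 0.0)
    a647, a664 = absorbance_from_lcc(lcc, ratio_647_to_664=config.absorbance_ratio)
    if config.absorbance_noise > 0:
        a647 = a647 * (1.0 + rng.normal(0.0, config.absorbance_noise, a647.shape))
        a664 = a664 * (1.0 + rng.normal(0.0, config.absorbance_noise, a664.shape))
    truth = {"nd": _truth_pair(spectra0, lcc, config, "ND"),
             "sr": _truth_pair(spectra0, lcc, config, "SR")}
    # CI = SR - 1: same bands/slope, intercept shifted by the slope
    truth["ci"] = dict(truth["sr"])
    truth["ci"]["intercept"] = truth["sr"]["intercept"] + truth["sr"]["slope"]
    sample_ids = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    return SyntheticDataset(
        spectra=noisy,
        axis=config.axis,
        lcc=lcc,
        a647=np.abs(a647),
        a664=np.abs(a664),
        sample_ids=sample_ids,
        truth=truth,
        config=config,
    )


def generate_cube(
    config: GeneratorConfig = GeneratorConfig(),
    layout: tuple[int, int] = (2, 3),
    footprint_px: tuple[int, int] = (10, 10),
    gap_px: int = 5,
    background_reflectance: float = 0.15,
    lcc_values: Sequence[float] | None = None,
) -> tuple[HyperCube, LeafMask, np.ndarray]:
    """Tray-style cube: a grid of rectangular leaf footprints on background.

    Each footprint carries one sample's spectrum (plus per-pixel noise);
    background pixels carry a flat spectrum.  Returns the cube, the
    ground-truth mask/labels, and the per-sample LCC values.
    """
    rng = np.random.default_rng(config.seed)
    n_rows, n_cols = layout
    n_samples = n_rows * n_cols
    if lcc_values is None:
        lo, hi = config.lcc_range
        lcc_values = rng.uniform(lo, hi, size=n_samples)
    lcc_values = np.asarray(lcc_values, dtype=float)
    if lcc_values.size != n_samples:
        raise ValueError("lcc_values length must equal rows*cols")
    fh, fw = footprint_px
    height = n_rows * (fh + gap_px) + gap_px
    width = n_cols * (fw + gap_px) + gap_px
    bands = len(config.axis)
    data = np.full((height, width, bands), background_reflectance)
    labels = np.zeros((height, width), dtype=int)
    for s in range(n_samples):
        r, c = divmod(s, n_cols)
        r0 = gap_px + r * (fh + gap_px)
        c0 = gap_px + c * (fw + gap_px)
        data[r0 : r0 + fh, c0 : c0 + fw, :] = generate_spectrum(lcc_values[s], config)
        labels[r0 : r0 + fh, c0 : c0 + fw] = s + 1
    if config.noise_sd > 0:
        data = np.maximum(data + rng.normal(0.0, config.noise_sd, data.shape), 0.0)
    cube = HyperCube(
        data,
        config.axis,
        meta={"synthetic": True, "layout": f"{n_rows}x{n_cols}", "seed": config.seed},
    )
    return cube, LeafMask(mask=labels > 0, sample_labels=labels), lcc_values
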