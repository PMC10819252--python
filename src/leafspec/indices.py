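"""Two-band vegetation indices and the linear LCC prediction model.

All indices combine reflectance at a longer band λi (NIR side) and a shorter
band λj:

    SR = Ri / Rj          (simple ratio)
    ND = (Ri - Rj) / (Ri + Rj)   (normalised difference)
    CI = Ri / Rj - 1      (chlorophyll index)

GNDVI is the ND index at a green λj (≈575 nm) and NIR λi (≈788 nm).  Band
lookups are nearest-centre (ties toward the shorter wavelength) rather than
interpolated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .cube import HyperCube, LeafMask, SpectralAxis

logger = logging.getLogger(__name__)

#: Closed enumeration of supported two-band index families.
VI_KINDS = ("ND", "SR", "CI")

DEFAULT_GREEN_NM = 575.0
DEFAULT_NIR_NM = 788.0


def compute_vi(r_i, r_j, kind: str):
    """Vegetation index from reflectance at λi (``r_i``) and λj (``r_j``).

    Accepts scalars or equally shaped arrays.  A zero denominator (Rj for
    SR/CI, Ri+Rj for ND) raises, identifying the offending positions.
    """
    kind = kind.upper()
    if kind not in VI_KINDS:
        raise ValueError(f"unknown VI kind '{kind}'; expected one of {VI_KINDS}")
    r_i = np.asarray(r_i, dtype=float)
    r_j = np.asarray(r_j, dtype=float)
    if np.any(~np.isfinite(r_i)) or np.any(~np.isfinite(r_j)):
        raise ValueError("reflectance inputs must be finite")
    if kind == "ND":
        denom = r_i + r_j
    else:
        denom = r_j
    bad = denom == 0
    if np.any(bad):
        where = np.nonzero(np.atleast_1d(bad))[0][:5].tolist()
        raise ZeroDivisionError(
            f"{kind} denominator is zero at positions {where}"
        )
    if kind == "SR":
        out = r_i / r_j
    elif kind == "CI":
        out = r_i / r_j - 1.0
    else:
        out = (r_i - r_j) / (r_i + r_j)
    return out if out.ndim else float(out)


def gndvi(
    spectrum,
    axis: SpectralAxis,
    green_nm: float = DEFAULT_GREEN_NM,
    nir_nm: float = DEFAULT_NIR_NM,
) -> float:
    """Green NDVI: ND of the nearest bands to ``nir_nm`` (λi) and ``green_nm`` (λj)."""
    spectrum = np.asarray(spectrum, dtype=float)
    i = axis.nearest(nir_nm)
    j = axis.nearest(green_nm)
    return float(compute_vi(spectrum[i], spectrum[j], "ND"))


@dataclass(frozen=True)
class PredictionModel:
    """Linear two-band VI → LCC model: ``lcc = slope * vi + intercept``."""

    vi: str
    lambda_i_nm: float
    lambda_j_nm: float
    slope: float
    intercept: float
    provenance: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.vi.upper() not in VI_KINDS and self.vi.upper() != "GNDVI":
            raise ValueError(f"unknown VI designation '{self.vi}'")
        for lam in (self.lambda_i_nm, self.lambda_j_nm):
            if not (450.0 <= lam <= 800.0):
                raise ValueError(f"band {lam} nm outside the 450-800 nm design range")
        if not np.isfinite(self.slope) or not np.isfinite(self.intercept):
            raise ValueError("model coefficients must be finite")

    @property
    def kind(self) -> str:
        """The VI family used for evaluation (GNDVI evaluates as ND)."""
        k = self.vi.upper()
        return "ND" if k == "GNDVI" else k

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        doc = {
            "vi": self.vi,
            "lambda_i_nm": self.lambda_i_nm,
            "lambda_j_nm": self.lambda_j_nm,
            "slope": self.slope,
            "intercept": self.intercept,
            "provenance": dict(self.provenance),
        }
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PredictionModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            vi=doc["vi"],
            lambda_i_nm=float(doc["lambda_i_nm"]),
            lambda_j_nm=float(doc["lambda_j_nm"]),
            slope=float(doc["slope"]),
            intercept=float(doc["intercept"]),
            provenance=doc.get("provenance", {}),
        )


#: The two-band GNDVI model reported for Chaew Khing rice:
#: LCC = 53.5 * GNDVI - 5.8 at 788/575 nm.
REFERENCE_GNDVI_MODEL = PredictionModel(
    vi="GNDVI",
    lambda_i_nm=DEFAULT_NIR_NM,
    lambda_j_nm=DEFAULT_GREEN_NM,
    slope=53.5,
    intercept=-5.8,
    provenance={"source": "published rice-leaf GNDVI calibration"},
)


def predict_lcc(vi_value, model: PredictionModel):
    """Predict LCC (µg·cm⁻²) from a VI value with a linear model.

    Negative predictions are physically impossible and are returned as-is but
    logged as flagged.
    """
    vi_value = np.asarray(vi_value, dtype=float)
    out = model.slope * vi_value + model.intercept
    n_neg = int(np.sum(out < 0))
    if n_neg:
        logger.warning(
            "%d negative LCC prediction(s) flagged (model %s %.0f/%.0f nm)",
            n_neg, model.vi, model.lambda_i_nm, model.lambda_j_nm,
        )
    return out if out.ndim else float(out)


def vi_map(cube: HyperCube, mask: LeafMask, model: PredictionModel) -> np.ndarray:
    """Per-pixel LCC map over masked pixels; background is NaN."""
    i = cube.axis.nearest(model.lambda_i_nm)
    j = cube.axis.nearest(model.lambda_j_nm)
    r_i = cube.data[:, :, i].astype(float)
    r_j = cube.data[:, :, j].astype(float)
    kind = model.kind
    with np.errstate(divide="ignore", invalid="ignore"):
        if kind == "ND":
            vi = (r_i - r_j) / (r_i + r_j)
        elif kind == "SR":
            vi = r_i / r_j
        else:
            vi = r_i / r_j - 1.0
    out = np.full(vi.shape, np.nan)
    sel = mask.mask
    out[sel] = model.slope * vi[sel] + model.intercept
    return out


def write_lcc_map(lcc_map: np.ndarray, path: str | Path) -> Path:
    """Write an LCC map as a single-band float32 TIFF (NaN background)."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, lcc_map.astype(np.float32))
    return path


def lcc_map_to_csv(lcc_map: np.ndarray, path: str | Path) -> Path:
    """Long-format CSV export (row, col, lcc) of the leaf pixels only."""
    import pandas as pd

    rows, cols = np.nonzero(np.isfinite(lcc_map))
    pd.DataFrame(
        {"row": rows, "col": cols, "lcc_ug_cm2": lcc_map[rows, cols]}
    ).to_csv(path, index=False, float_format="%.6g")
    return Path(path)
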