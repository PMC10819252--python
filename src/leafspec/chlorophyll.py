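"""Leaf chlorophyll content (LCC) from spectrophotometric absorbance.

Leaf discs are extracted in N,N-dimethylformamide (DMF) and the extract's
absorbance read at 647 nm and 664 nm.  Total chlorophyll per unit leaf area is

    LCC = (20.27 * A647 + 7.04 * A664) * V / (n_discs * disc_area)

in µg·cm⁻², with extract volume V in mL and disc area in cm².  The 20.27/7.04
coefficients are DMF-specific spectrophotometric constants; the geometric
factor defaults to 4 mL over two 0.82 cm² discs (≈ 2.439 cm⁻²·mL).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

#: DMF extract coefficients (µg·mL⁻¹ per absorbance unit).
COEFF_A647 = 20.27
COEFF_A664 = 7.04

DEFAULT_VOLUME_ML = 4.0
DEFAULT_DISCS = 2
DEFAULT_DISC_AREA_CM2 = 0.82


def lcc_from_absorbance(
    a647,
    a664,
    extract_volume_ml: float = DEFAULT_VOLUME_ML,
    discs: int = DEFAULT_DISCS,
    disc_area_cm2: float = DEFAULT_DISC_AREA_CM2,
):
    """Total chlorophyll per leaf area (µg·cm⁻²) from a DMF absorbance pair.

    Accepts scalars or arrays; both absorbances must be finite and
    non-negative.
    """
    a647 = np.asarray(a647, dtype=float)
    a664 = np.asarray(a664, dtype=float)
    if np.any(~np.isfinite(a647)) or np.any(~np.isfinite(a664)):
        raise ValueError("absorbances must be finite")
    if np.any(a647 < 0) or np.any(a664 < 0):
        raise ValueError("absorbances must be non-negative")
    if extract_volume_ml <= 0 or discs < 1 or disc_area_cm2 <= 0:
        raise ValueError("extraction geometry must be positive")
    lcc = (COEFF_A647 * a647 + COEFF_A664 * a664) * extract_volume_ml / (
        discs * disc_area_cm2
    )
    return lcc if lcc.ndim else float(lcc)


def absorbance_from_lcc(
    lcc,
    ratio_647_to_664: float = 0.4,
    extract_volume_ml: float = DEFAULT_VOLUME_ML,
    discs: int = DEFAULT_DISCS,
    disc_area_cm2: float = DEFAULT_DISC_AREA_CM2,
):
    """Invert the LCC formula under a fixed A647:A664 ratio.

    The forward map is scalar-valued and therefore underdetermined; fixing the
    absorbance ratio (default 0.4, a typical DMF-extract proportion) selects
    the unique pre-image.  Returns ``(a647, a664)``.
    """
    lcc = np.asarray(lcc, dtype=float)
    if np.any(lcc < 0) or np.any(~np.isfinite(lcc)):
        raise ValueError("LCC must be finite and non-negative")
    if ratio_647_to_664 <= 0:
        raise ValueError("absorbance ratio must be positive")
    geometry = extract_volume_ml / (discs * disc_area_cm2)
    a664 = lcc / ((COEFF_A647 * ratio_647_to_664 + COEFF_A664) * geometry)
    a647 = ratio_647_to_664 * a664
    if lcc.ndim:
        return a647, a664
    return float(a647), float(a664)


def read_chlorophyll_table(
    path: str | Path,
    extract_volume_ml: float = DEFAULT_VOLUME_ML,
    discs: int = DEFAULT_DISCS,
    disc_area_cm2: float = DEFAULT_DISC_AREA_CM2,
) -> pd.DataFrame:
    """Read a per-sample chemistry CSV, deriving whichever column is absent.

    Expected columns: ``sample_id`` plus either (``a647``, ``a664``) or
    ``lcc_ug_cm2`` (or both).  A missing LCC column is derived from the
    absorbances; missing absorbances are derived from LCC at the default
    ratio.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError("chemistry CSV must have a sample_id column")
    df["sample_id"] = df["sample_id"].astype(str)
    has_abs = {"a647", "a664"}.issubset(df.columns)
    has_lcc = "lcc_ug_cm2" in df.columns
    if not has_abs and not has_lcc:
        raise ValueError(
            "chemistry CSV needs either a647/a664 or lcc_ug_cm2 columns"
        )
    if not has_lcc:
        df["lcc_ug_cm2"] = lcc_from_absorbance(
            df["a647"].to_numpy(), df["a664"].to_numpy(),
            extract_volume_ml, discs, disc_area_cm2,
        )
    if not has_abs:
        a647, a664 = absorbance_from_lcc(
            df["lcc_ug_cm2"].to_numpy(),
            extract_volume_ml=extract_volume_ml,
            discs=discs,
            disc_area_cm2=disc_area_cm2,
        )
        df["a647"], df["a664"] = a647, a664
    return df[["sample_id", "a647", "a664", "lcc_ug_cm2"]]


def write_chlorophyll_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.10g")
    return path
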