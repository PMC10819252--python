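"""Hyperspectral cube containers, I/O, reflectance calibration and region reduction.

A cube is a 3-D reflectance array indexed ``(row, col, band)`` with a calibrated
wavelength axis in nanometres.  Two on-disk formats are supported:

* a minimal ENVI dialect — plain-text ``.hdr`` beside a raw binary file,
  lowercase keys, a mandatory ``wavelength`` block, interleave one of
  ``bsq``/``bil``/``bip``;
* an ``.npz`` container (data + wavelengths + JSON metadata) used for compact
  self-describing fixtures.

Reflectance is computed from raw/white/dark frames as
``R = (raw - dark) / (white - dark)``; negative values are clamped to zero,
values above one are kept (specular glints) but counted in the metadata, and
pixels where the white reference does not exceed the dark frame are set to NaN.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage


class CubeFormatError(ValueError):
    """Raised when a cube file is malformed or inconsistent with its header."""


class SegmentationError(ValueError):
    """Raised when leaf segmentation produces an empty mask."""


# ENVI data-type codes for the subset of dtypes this package writes.
_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass(frozen=True)
class SpectralAxis:
    """Band-centre wavelengths in nm, strictly increasing."""

    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("spectral axis needs at least two band centres")
        if not np.all(np.isfinite(wl)):
            raise ValueError("spectral axis contains non-finite wavelengths")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("spectral axis must be strictly increasing")
        object.__setattr__(self, "wavelengths_nm", wl)

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    def nearest(self, target_nm: float) -> int:
        """Index of the band centre nearest ``target_nm``.

        Ties are broken toward the shorter wavelength (``argmin`` returns the
        first minimum on an increasing axis).
        """
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        if not (lo <= target_nm <= hi):
            raise ValueError(
                f"wavelength {target_nm} nm outside axis range [{lo}, {hi}] nm"
            )
        return int(np.argmin(np.abs(self.wavelengths_nm - target_nm)))

    def window(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Indices of band centres inside ``[lo_nm, hi_nm]`` (inclusive)."""
        if hi_nm <= lo_nm:
            raise ValueError(f"empty wavelength window ({lo_nm}, {hi_nm})")
        wl = self.wavelengths_nm
        return np.nonzero((wl >= lo_nm) & (wl <= hi_nm))[0]

    def restrict(self, indices: np.ndarray) -> "SpectralAxis":
        return SpectralAxis(self.wavelengths_nm[np.asarray(indices)])


@dataclass
class HyperCube:
    """Reflectance cube ``data[row, col, band]`` with its wavelength axis."""

    data: np.ndarray
    axis: SpectralAxis
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (row, col, band)")
        if self.data.shape[2] != len(self.axis):
            raise ValueError(
                f"cube has {self.data.shape[2]} bands but axis has {len(self.axis)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LeafMask:
    """Boolean vegetation mask plus integer sample labels (0 = background)."""

    mask: np.ndarray
    sample_labels: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.sample_labels = np.asarray(self.sample_labels, dtype=int)
        if self.mask.shape != self.sample_labels.shape:
            raise ValueError("mask and labels must share shape")
        if np.any((self.sample_labels > 0) & ~self.mask):
            raise ValueError("labelled pixels must be a subset of mask-true pixels")

    @property
    def sample_ids(self) -> np.ndarray:
        ids = np.unique(self.sample_labels)
        return ids[ids > 0]


# ---------------------------------------------------------------------------
# ENVI + npz I/O


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise CubeFormatError("not an ENVI header (missing magic word)")
    body = text.lstrip()[4:]
    # key = value, where value may be a {...} block spanning lines
    header: dict = {}
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{"):
            val = val[1:-1].strip()
        header[key] = val
    return header


def _read_envi(path: Path) -> HyperCube:
    path = Path(path)
    if path.suffix == ".hdr":
        hdr_path, data_path = path, path.with_suffix("")
    else:
        hdr_path, data_path = Path(str(path) + ".hdr"), path
    if not hdr_path.exists():
        raise CubeFormatError(f"missing ENVI header {hdr_path}")
    header = _parse_envi_header(hdr_path.read_text())

    for key in ("samples", "lines", "bands", "data type", "interleave"):
        if key not in header:
            raise CubeFormatError(f"ENVI header missing required key '{key}'")
    if "wavelength" not in header:
        raise CubeFormatError(
            "ENVI header has no 'wavelength' block; refusing to invent an index axis"
        )
    samples = int(header["samples"])  # columns
    lines = int(header["lines"])  # rows
    bands = int(header["bands"])
    interleave = header["interleave"].lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise CubeFormatError(f"unsupported interleave '{interleave}'")
    code = int(header["data type"])
    if code not in _ENVI_DTYPES:
        raise CubeFormatError(f"unsupported ENVI data type code {code}")
    dtype = np.dtype(_ENVI_DTYPES[code])
    if int(header.get("byte order", "0")) != 0:
        dtype = dtype.newbyteorder(">")

    wl = np.array([float(t) for t in header["wavelength"].split(",") if t.strip()])
    if wl.size != bands:
        raise CubeFormatError(
            f"header declares {bands} bands but lists {wl.size} wavelengths"
        )

    raw = np.fromfile(data_path, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise CubeFormatError(
            f"binary holds {raw.size} values, header implies {expected} "
            f"({lines}x{samples}x{bands})"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        data = raw.reshape(lines, samples, bands)

    meta = {k: v for k, v in header.items()
            if k not in ("samples", "lines", "bands", "data type", "interleave",
                         "wavelength", "byte order", "header offset")}
    meta["source"] = str(data_path)
    return HyperCube(np.ascontiguousarray(data, dtype=float), SpectralAxis(wl), meta)


def _read_npz(path: Path) -> HyperCube:
    with np.load(path, allow_pickle=False) as npz:
        if "data" not in npz or "wavelengths_nm" not in npz:
            raise CubeFormatError("npz container missing 'data'/'wavelengths_nm'")
        data = npz["data"]
        wl = npz["wavelengths_nm"]
        meta = json.loads(str(npz["meta_json"])) if "meta_json" in npz else {}
    if data.ndim != 3:
        raise CubeFormatError("npz cube data is not 3-D")
    if data.shape[2] != wl.size:
        raise CubeFormatError(
            f"npz cube has {data.shape[2]} bands but {wl.size} wavelengths"
        )
    meta["source"] = str(path)
    return HyperCube(data, SpectralAxis(wl), meta)


def read_cube(path: str | Path, format: str | None = None) -> HyperCube:
    """Read a cube from ENVI (``format='envi'``) or npz container files.

    When ``format`` is omitted it is inferred from the file extension
    (``.npz`` → container, anything else → ENVI).
    """
    path = Path(path)
    if format is None:
        format = "npz-container" if path.suffix == ".npz" else "envi"
    if format == "envi":
        return _read_envi(path)
    if format in ("npz", "npz-container"):
        return _read_npz(path)
    raise ValueError(f"unknown cube format '{format}'")


def write_cube(
    cube: HyperCube,
    path: str | Path,
    format: str | None = None,
    interleave: str = "bsq",
    dtype: str | np.dtype = np.float64,
) -> Path:
    """Write a cube as ENVI header+binary or as an npz container."""
    path = Path(path)
    if format is None:
        format = "npz-container" if path.suffix == ".npz" else "envi"
    if format in ("npz", "npz-container"):
        np.savez_compressed(
            path,
            data=cube.data,
            wavelengths_nm=cube.axis.wavelengths_nm,
            meta_json=json.dumps({k: v for k, v in cube.meta.items()
                                  if isinstance(v, (str, int, float, bool))}),
        )
        return path
    if format != "envi":
        raise ValueError(f"unknown cube format '{format}'")
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unsupported interleave '{interleave}'")
    dtype = np.dtype(dtype)
    if dtype not in _ENVI_CODES:
        raise ValueError(f"unsupported ENVI dtype {dtype}")
    rows, cols, bands = cube.data.shape
    arr = cube.data.astype(dtype)
    if interleave == "bsq":
        out = arr.transpose(2, 0, 1)
    elif interleave == "bil":
        out = arr.transpose(0, 2, 1)
    else:
        out = arr
    out.tofile(path)
    wl = ", ".join(f"{w:.6f}" for w in cube.axis.wavelengths_nm)
    hdr = (
        "ENVI\n"
        "description = {leafspec reflectance cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    Path(str(path) + ".hdr").write_text(hdr)
    return path


# ---------------------------------------------------------------------------
# Calibration and reduction


def reflectance_calibrate(raw: HyperCube, white: HyperCube, dark: HyperCube) -> HyperCube:
    """Two-point reflectance calibration ``R = (raw - dark) / (white - dark)``.

    Pixels where the white reference does not exceed the dark frame are invalid
    and set to NaN.  Negative reflectance is clamped to zero; values above one
    are preserved but counted in ``meta['n_above_one']``.
    """
    for other in (white, dark):
        if other.data.shape != raw.data.shape:
            raise ValueError("raw/white/dark cubes must share dimensions")
        if not np.array_equal(other.axis.wavelengths_nm, raw.axis.wavelengths_nm):
            raise ValueError("raw/white/dark cubes must share the wavelength axis")
    denom = white.data - dark.data
    invalid = denom <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = (raw.data - dark.data) / denom
    refl = np.where(invalid, np.nan, refl)
    n_negative = int(np.sum(refl < 0))
    refl = np.where(refl < 0, 0.0, refl)
    meta = dict(raw.meta)
    meta.update(
        calibration="(raw - dark) / (white - dark)",
        n_invalid=int(invalid.sum()),
        n_clamped_negative=n_negative,
        n_above_one=int(np.nansum(refl > 1)),
    )
    return HyperCube(refl, raw.axis, meta)


def normalized_difference_image(
    cube: HyperCube, nir_nm: float, red_nm: float
) -> np.ndarray:
    """Per-pixel ND(nir, red) image using nearest band centres."""
    r_nir = cube.data[:, :, cube.axis.nearest(nir_nm)]
    r_red = cube.data[:, :, cube.axis.nearest(red_nm)]
    with np.errstate(divide="ignore", invalid="ignore"):
        nd = (r_nir - r_red) / (r_nir + r_red)
    return nd


def segment_leaf(
    cube: HyperCube,
    red_nm: float = 670.0,
    nir_nm: float = 780.0,
    threshold: float = 0.3,
    min_pixels: int = 10,
) -> LeafMask:
    """Vegetation segmentation by thresholding ND(NIR, red).

    Connected components (4-connectivity) are labelled in raster order of their
    first pixel; components smaller than ``min_pixels`` are dropped from the
    labels (but remain in the boolean mask).
    """
    nd = normalized_difference_image(cube, nir_nm=nir_nm, red_nm=red_nm)
    mask = np.where(np.isfinite(nd), nd, -np.inf) > threshold
    if not mask.any():
        raise SegmentationError(
            f"no pixel exceeds ND threshold {threshold}; "
            "lower the threshold or check the band choice"
        )
    raw_labels, n_raw = ndimage.label(mask)
    labels = np.zeros_like(raw_labels)
    next_id = 1
    for lab in range(1, n_raw + 1):
        component = raw_labels == lab
        if component.sum() >= min_pixels:
            labels[component] = next_id
            next_id += 1
    return LeafMask(mask=mask, sample_labels=labels)


def mean_spectrum(
    cube: HyperCube, mask: LeafMask, sample_id: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-band mean and population sd over one labelled sample region.

    Invalid (NaN) pixel values are excluded band-wise.  Returns
    ``(mean, sd, n_pixels)``.
    """
    region = mask.sample_labels == sample_id
    n = int(region.sum())
    if n == 0:
        raise ValueError(f"sample id {sample_id} has no labelled pixels")
    pixels = cube.data[region]  # (n_pixels, bands)
    mean = np.nanmean(pixels, axis=0)
    sd = np.nanstd(pixels, axis=0)
    return mean, sd, n


def extract_sample_spectra(
    cube: HyperCube, mask: LeafMask, id_prefix: str = "S"
) -> pd.DataFrame:
    """Mean spectra of every labelled sample, long format.

    Columns: ``sample_id, wavelength_nm, mean_reflectance, sd_reflectance``.
    """
    frames = []
    wl = cube.axis.wavelengths_nm
    for sid in mask.sample_ids:
        mean, sd, _ = mean_spectrum(cube, mask, int(sid))
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": f"{id_prefix}{sid:03d}",
                    "wavelength_nm": wl,
                    "mean_reflectance": mean,
                    "sd_reflectance": sd,
                }
            )
        )
    if not frames:
        raise ValueError("mask contains no labelled samples")
    return pd.concat(frames, ignore_index=True)


def write_spectra_csv(spectra: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    spectra.to_csv(path, index=False, float_format="%.10g")
    return path


def read_spectra_csv(path: str | Path) -> tuple[pd.DataFrame, SpectralAxis]:
    """Read a long-format spectra CSV into a wide samples x bands table.

    Returns ``(table, axis)`` where the table is indexed by sample_id with one
    column per wavelength.
    """
    long = pd.read_csv(path)
    required = {"sample_id", "wavelength_nm", "mean_reflectance"}
    if not required.issubset(long.columns):
        raise ValueError(f"spectra CSV must have columns {sorted(required)}")
    wide = long.pivot_table(
        index="sample_id", columns="wavelength_nm", values="mean_reflectance"
    ).sort_index(axis=1)
    axis = SpectralAxis(wide.columns.to_numpy(dtype=float))
    return wide, axis


def write_label_image(mask: LeafMask, path: str | Path) -> Path:
    """Export sample labels as a single-band integer TIFF."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, mask.sample_labels.astype(np.int32))
    return path
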