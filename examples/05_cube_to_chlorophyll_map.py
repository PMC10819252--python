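"""From a hyperspectral cube to a per-pixel chlorophyll map.

Builds a small synthetic tray cube (six leaf pieces on a grey background),
segments vegetation by thresholding ND(780, 670), reduces each sample to its
mean spectrum, and finally applies a two-band ND model calibrated on the same
generator (the planted VI→LCC law) pixel-wise to map chlorophyll across the
leaves.  For real rice-leaf cubes the published calibration
``REFERENCE_GNDVI_MODEL`` (LCC = 53.5 x GNDVI - 5.8) would be used instead.
Outputs land in a temporary directory.
"""

import tempfile
from pathlib import Path

import numpy as np

from leafspec import (
    GeneratorConfig,
    PredictionModel,
    extract_sample_spectra,
    generate_cube,
    generate_dataset,
    predict_on_cube,
    segment_leaf,
    write_cube,
)

outdir = Path(tempfile.mkdtemp(prefix="leafspec_"))
cfg = GeneratorConfig(n_bands=100, seed=4)
cube, truth_mask, lcc = generate_cube(cfg, layout=(2, 3), footprint_px=(8, 8))
print(f"cube: {cube.shape[0]}x{cube.shape[1]} px, {cube.shape[2]} bands; "
      f"planted LCC {np.round(lcc, 1)}")

mask = segment_leaf(cube)
print(f"segmented {mask.sample_ids.size} samples, "
      f"{int(mask.mask.sum())} leaf pixels")

spectra = extract_sample_spectra(cube, mask)
print(f"mean spectra table: {spectra['sample_id'].nunique()} samples x "
      f"{spectra['wavelength_nm'].nunique()} bands")

cube_path = outdir / "cube.npz"
write_cube(cube, cube_path)
# calibrate the two-band model on a dataset from the same generator
ds = generate_dataset(cfg)
t = ds.truth["nd"]
model = PredictionModel("ND", t["lambda_i_nm"], t["lambda_j_nm"],
                        slope=t["slope"], intercept=t["intercept"])
model_path = outdir / "model.json"
model.to_json(model_path)
summary = predict_on_cube(cube_path, model_path, outdir / "lcc_map")
print(f"LCC map over leaf pixels: mean {summary['mean_lcc_ug_cm2']:.2f} "
      f"± {summary['sd_lcc_ug_cm2']:.2f} ug/cm^2 "
      f"(planted mean {lcc.mean():.2f})")
print(f"outputs in {outdir}")
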