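"""Exhaustive two-band search: grids, centroid bands, final model.

Runs the cross-validated band-pair search for all three VI families on a
reduced 50-band axis (fast; the full 351-band grid works identically), picks
optimal bands as the centroid of the top-R² contour region, and fits the
final two-band LCC model.  Note the SR and CI rows: CI = SR - 1 is an affine
predictor map, so their statistics agree to machine precision.
"""

from leafspec import (
    GeneratorConfig,
    fit_final_model,
    generate_dataset,
    kfold_cv,
    pair_search,
    strength_label,
    top_region_centroid,
)
from leafspec.indices import compute_vi

ds = generate_dataset(GeneratorConfig(n_bands=50, seed=1))
print(f"{'VI':3s} {'λi ± (nm)':>16s} {'λj ± (nm)':>16s} "
      f"{'CV R²':>7s} {'RMSE':>6s} {'r':>6s}  strength")
for vi in ("ND", "SR", "CI"):
    grid = pair_search(ds.spectra, ds.axis, ds.lcc, vi, k=10, seed=1)
    c = top_region_centroid(grid, delta=0.01)
    model, fit = fit_final_model(ds.spectra, ds.axis, ds.lcc, vi, c)
    i = ds.axis.nearest(model.lambda_i_nm)
    j = ds.axis.nearest(model.lambda_j_nm)
    cv = kfold_cv(compute_vi(ds.spectra[:, i], ds.spectra[:, j], vi), ds.lcc,
                  k=10, seed=1)
    print(f"{vi:3s} {c.cx_nm:8.1f} ± {c.half_width_i_nm:4.1f} "
          f"{c.cy_nm:8.1f} ± {c.half_width_j_nm:4.1f} "
          f"{cv.mean_r2:7.3f} {cv.mean_rmse:6.2f} {fit.r:6.2f}  "
          f"{strength_label(fit.r)}")
    if vi == "ND":
        print(f"    model: LCC = {model.slope:.2f} x ND + {model.intercept:.2f}  "
              f"(truth: {ds.truth['nd']['slope']:.2f}, "
              f"{ds.truth['nd']['intercept']:.2f})")
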