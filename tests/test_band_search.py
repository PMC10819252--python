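"""OLS regression, cross-validation, grid search and centroid selection."""

import numpy as np
import pytest

from leafspec import (
    GeneratorConfig,
    SpectralAxis,
    fit_final_model,
    fold_indices,
    generate_dataset,
    kfold_cv,
    ols_fit,
    pair_search,
    strength_label,
    top_region_centroid,
)
from leafspec.band_search import BandPairGrid, top_region


def _normal_equations_oracle(x, y):
    """Independent least-squares reference: design-matrix lstsq + naive metrics."""
    X = np.column_stack([np.ones_like(x), x])
    (b0, b1), *_ = np.linalg.lstsq(X, y, rcond=None)
    pred = b0 + b1 * x
    ss_res = np.sum((y - pred) ** 2)
    ss_tot = np.sum((y - np.mean(y)) ** 2)
    r = np.corrcoef(x, y)[0, 1]
    return b1, b0, 1 - ss_res / ss_tot, np.sqrt(ss_res / len(x)), r


class TestOLS:
    def test_perfect_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = ols_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)
        assert fit.r == pytest.approx(1.0)

    def test_perfect_negative_line(self):
        x = np.linspace(0, 5, 7)
        assert ols_fit(x, -3 * x + 5).r == pytest.approx(-1.0)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(50):
            x = rng.uniform(-2, 2, 6)
            y = rng.uniform(-5, 5, 6)
            fit = ols_fit(x, y)
            b1, b0, r2, rmse, r = _normal_equations_oracle(x, y)
            assert fit.slope == pytest.approx(b1, abs=1e-10)
            assert fit.intercept == pytest.approx(b0, abs=1e-10)
            assert fit.r2 == pytest.approx(r2, abs=1e-10)
            assert fit.rmse == pytest.approx(rmse, abs=1e-10)
            assert fit.r == pytest.approx(r, abs=1e-10)

    def test_insample_r2_equals_r_squared(self, rng):
        x = rng.uniform(0, 1, 30)
        y = 3 * x + rng.normal(0, 0.5, 30)
        fit = ols_fit(x, y)
        assert fit.r2 == pytest.approx(fit.r**2, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ZeroDivisionError):
            ols_fit(np.ones(5), np.arange(5.0))
        with pytest.raises(ZeroDivisionError):
            ols_fit(np.arange(5.0), np.ones(5))
        with pytest.raises(ValueError):
            ols_fit(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestKFold:
    def test_fold_sizes_and_exhaustive_coverage(self):
        for seed in range(20):
            folds = fold_indices(120, 10, seed)
            assert all(f.size == 12 for f in folds)
            assert sorted(np.concatenate(folds)) == list(range(120))

    def test_uneven_split_differs_by_at_most_one(self):
        sizes = [f.size for f in fold_indices(23, 5, 0)]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == 23

    def test_noiseless_linear_data_scores_perfectly(self, rng):
        x = rng.uniform(0, 1, 40)
        y = 5 * x - 2
        for seed in (0, 1, 2):
            cv = kfold_cv(x, y, k=10, seed=seed)
            assert cv.mean_r2 == pytest.approx(1.0, abs=1e-12)
            assert cv.mean_rmse == pytest.approx(0.0, abs=1e-9)

    def test_n_smaller_than_k_errors(self):
        with pytest.raises(ValueError):
            kfold_cv(np.arange(5.0), np.arange(5.0), k=10, seed=0)

    def test_pooled_variant_reports_extra_metrics(self, rng):
        x = rng.uniform(0, 1, 50)
        y = 2 * x + rng.normal(0, 0.2, 50)
        cv = kfold_cv(x, y, k=5, seed=3, pooled=True)
        assert cv.pooled_r2 is not None and 0 < cv.pooled_r2 <= 1
        assert cv.pooled_rmse is not None and cv.pooled_rmse > 0

    def test_mean_validation_r2_near_analytic_value(self):
        # y = x + e with var(x)=1, var(e)=0.25: population R^2 = 0.8.  The
        # held-out-fold estimate carries three finite-sample corrections:
        # fold-mean SStot (n_v/(n_v-1)), training-coefficient inflation
        # (1+2/n_train), and the SSres/SStot ratio bias (1+2/(n_v-1)), giving
        # E[R^2_val] ~ 1 - 0.2*(20/19)*(1+2/180)*(1+2/19) = 0.7647
        rng = np.random.default_rng(99)
        vals = []
        for _ in range(200):
            x = rng.normal(0, 1.0, 200)
            y = x + rng.normal(0, 0.5, 200)
            vals.append(kfold_cv(x, y, k=10, seed=0).mean_r2)
        expected = 1 - 0.2 * (20 / 19) * (1 + 2 / 180) * (1 + 2 / 19)
        assert np.mean(vals) == pytest.approx(expected, abs=0.01)


class TestPairSearch:
    def test_three_band_grid_structure(self, rng):
        axis = SpectralAxis(np.array([500.0, 600.0, 700.0]))
        spectra = rng.uniform(0.1, 0.9, (20, 3))
        lcc = rng.uniform(4, 23, 20)
        grid = pair_search(spectra, axis, lcc, "ND", k=5, seed=0)
        assert grid.r2_grid.shape == (3, 3)
        assert np.isnan(np.diag(grid.r2_grid)).all()
        assert grid.excluded.trace() == 3
        assert np.isfinite(grid.r2_grid[0, 1])

    def test_matches_scalar_kfold_cell_for_cell(self, small_dataset):
        ds = small_dataset
        grid = pair_search(ds.spectra, ds.axis, ds.lcc, "ND", k=10, seed=5)
        from leafspec import compute_vi

        for i, j in [(2, 30), (35, 10), (17, 18)]:
            x = compute_vi(ds.spectra[:, i], ds.spectra[:, j], "ND")
            cv = kfold_cv(x, ds.lcc, k=10, seed=5)
            assert grid.r2_grid[i, j] == pytest.approx(cv.mean_r2, abs=1e-10)
            assert grid.rmse_grid[i, j] == pytest.approx(cv.mean_rmse, abs=1e-10)
            fit = ols_fit(x, ds.lcc)
            assert grid.r_grid[i, j] == pytest.approx(fit.r, abs=1e-10)

    def test_sr_and_ci_grids_agree_cell_for_cell(self, small_dataset):
        ds = small_dataset
        sr = pair_search(ds.spectra, ds.axis, ds.lcc, "SR", k=10, seed=2)
        ci = pair_search(ds.spectra, ds.axis, ds.lcc, "CI", k=10, seed=2)
        np.testing.assert_allclose(sr.r2_grid, ci.r2_grid, atol=1e-10)
        np.testing.assert_allclose(sr.rmse_grid, ci.rmse_grid, atol=1e-10)
        np.testing.assert_allclose(sr.r_grid, ci.r_grid, atol=1e-10)

    def test_bit_reproducible_with_fixed_seed(self, small_dataset):
        ds = small_dataset
        a = pair_search(ds.spectra, ds.axis, ds.lcc, "ND", k=10, seed=9)
        b = pair_search(ds.spectra, ds.axis, ds.lcc, "ND", k=10, seed=9)
        np.testing.assert_array_equal(a.r2_grid, b.r2_grid)

    def test_noiseless_dataset_scores_near_one_at_truth_pair(self):
        cfg = GeneratorConfig(n_bands=40, n_samples=60, seed=21, noise_sd=0.0,
                              absorbance_noise=0.0)
        ds = generate_dataset(cfg)
        grid = pair_search(ds.spectra, ds.axis, ds.lcc, "ND", k=10, seed=0)
        i = ds.axis.nearest(ds.truth["nd"]["lambda_i_nm"])
        j = ds.axis.nearest(ds.truth["nd"]["lambda_j_nm"])
        assert grid.r2_grid[i, j] > 0.999

    def test_long_format_export(self, small_dataset, tmp_path):
        import pandas as pd

        ds = small_dataset
        grid = pair_search(ds.spectra, ds.axis, ds.lcc, "ND", k=10, seed=0)
        grid.to_csv(tmp_path / "g.csv")
        df = pd.read_csv(tmp_path / "g.csv")
        assert list(df.columns) == [
            "vi", "lambda_i_nm", "lambda_j_nm", "mean_r2", "mean_rmse", "r",
            "n_excluded",
        ]
        assert len(df) == len(ds.axis) ** 2


def _grid_from_r2(r2, wl_i=None, wl_j=None):
    ni, nj = r2.shape
    wl_i = np.arange(ni, dtype=float) + 500 if wl_i is None else wl_i
    wl_j = np.arange(nj, dtype=float) + 600 if wl_j is None else wl_j
    nan = np.full_like(r2, np.nan)
    return BandPairGrid(
        vi="ND", axis_i=SpectralAxis(wl_i), axis_j=SpectralAxis(wl_j),
        r2_grid=r2, rmse_grid=nan, r_grid=nan,
        excluded=~np.isfinite(r2), n_nonfinite=np.zeros(r2.shape, dtype=int),
        k=10, seed=0, n_samples=100,
    )


class TestCentroid:
    def test_single_cell_region(self):
        r2 = np.full((5, 5), 0.2)
        r2[2, 3] = 0.9
        c = top_region_centroid(_grid_from_r2(r2), delta=0.01)
        assert c.cx_nm == pytest.approx(502.0)
        assert c.cy_nm == pytest.approx(603.0)
        assert c.region_cells == 1
        assert c.m00 == 1.0
        assert c.half_width_i_nm == 0.0

    def test_symmetric_plateau_centroid_at_centre(self):
        r2 = np.full((9, 9), 0.1)
        r2[3:6, 3:6] = 0.8  # 3x3 plateau centred at (504, 604)
        c = top_region_centroid(_grid_from_r2(r2), delta=0.01)
        assert c.cx_nm == pytest.approx(504.0)
        assert c.cy_nm == pytest.approx(604.0)
        assert c.region_cells == 9

    def test_moments_match_brute_force_double_loop(self, rng):
        for _ in range(20):
            r2 = rng.uniform(0, 1, (20, 20))
            grid = _grid_from_r2(r2)
            delta = 0.02
            c = top_region_centroid(grid, delta=delta)
            region = top_region(grid, delta=delta)
            m00 = m10 = m01 = 0.0
            for i in range(20):
                for j in range(20):
                    if region[i, j]:
                        m00 += 1.0
                        m10 += grid.axis_i.wavelengths_nm[i]
                        m01 += grid.axis_j.wavelengths_nm[j]
            assert c.m00 == m00
            assert c.m10 == m10
            assert c.m01 == m01
            assert c.cx_nm == pytest.approx(m10 / m00, abs=1e-12)
            assert c.cy_nm == pytest.approx(m01 / m00, abs=1e-12)

    def test_centroid_inside_region_bounding_box(self, rng):
        r2 = rng.uniform(0, 1, (15, 15))
        grid = _grid_from_r2(r2)
        c = top_region_centroid(grid, delta=0.05)
        region = top_region(grid, delta=0.05)
        ii, jj = np.nonzero(region)
        li = grid.axis_i.wavelengths_nm[ii]
        lj = grid.axis_j.wavelengths_nm[jj]
        assert li.min() <= c.cx_nm <= li.max()
        assert lj.min() <= c.cy_nm <= lj.max()

    def test_mirrored_nd_blobs_do_not_collapse_to_diagonal(self):
        # two exactly tied blobs mirrored across the diagonal, as ND produces
        wl = np.arange(10, dtype=float) + 700
        r2 = np.full((10, 10), 0.1)
        r2[7:9, 1:3] = 0.9  # λi > λj blob
        r2[1:3, 7:9] = 0.9  # mirrored blob
        c = top_region_centroid(_grid_from_r2(r2, wl, wl), delta=0.01)
        assert c.cx_nm > c.cy_nm  # NIR-over-green orientation kept
        assert c.region_cells == 4

    def test_all_excluded_errors(self):
        r2 = np.full((4, 4), np.nan)
        with pytest.raises(ValueError):
            top_region_centroid(_grid_from_r2(r2))


class TestStrengthLabel:
    @pytest.mark.parametrize("r,label", [
        (0.05, "negligible"), (0.87, "strong"), (-0.95, "very strong"),
        (0.25, "weak"), (0.55, "moderate"),
        # boundary rule: edge values go to the higher-strength bin
        (0.10, "weak"), (0.40, "moderate"), (0.70, "strong"), (0.90, "very strong"),
        (1.0, "very strong"), (0.0, "negligible"),
    ])
    def test_bins(self, r, label):
        assert strength_label(r) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            strength_label(1.5)


class TestFinalModel:
    def test_recovers_planted_linear_law_exactly(self):
        cfg = GeneratorConfig(n_bands=40, n_samples=60, seed=13)
        ds = generate_dataset(cfg)
        grid = pair_search(ds.spectra, ds.axis, ds.lcc, "ND", k=10, seed=0)
        centroid = top_region_centroid(grid)
        # plant an exactly linear VI→LCC law at the selected bands
        from leafspec import compute_vi

        i = ds.axis.nearest(centroid.cx_nm)
        j = ds.axis.nearest(centroid.cy_nm)
        x = compute_vi(ds.spectra[:, i], ds.spectra[:, j], "ND")
        y = 40.0 * x + 3.0
        model2, fit2 = fit_final_model(ds.spectra, ds.axis, y, "ND", centroid)
        assert model2.slope == pytest.approx(40.0, abs=1e-8)
        assert model2.intercept == pytest.approx(3.0, abs=1e-8)
        assert fit2.r2 == pytest.approx(1.0, abs=1e-12)

    def test_permutation_invariance(self, small_dataset):
        ds = small_dataset
        grid = pair_search(ds.spectra, ds.axis, ds.lcc, "ND", k=10, seed=0)
        centroid = top_region_centroid(grid)
        model, _ = fit_final_model(ds.spectra, ds.axis, ds.lcc, "ND", centroid)
        perm = np.random.default_rng(0).permutation(ds.lcc.size)
        model_p, _ = fit_final_model(
            ds.spectra[perm], ds.axis, ds.lcc[perm], "ND", centroid
        )
        assert model_p.slope == pytest.approx(model.slope, rel=1e-12)
        assert model_p.intercept == pytest.approx(model.intercept, rel=1e-12)

    def test_slope_sign_matches_correlation(self, small_dataset):
        ds = small_dataset
        grid = pair_search(ds.spectra, ds.axis, ds.lcc, "ND", k=10, seed=0)
        centroid = top_region_centroid(grid)
        model, fit = fit_final_model(ds.spectra, ds.axis, ds.lcc, "ND", centroid)
        assert np.sign(model.slope) == np.sign(fit.r)
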