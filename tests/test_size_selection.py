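import warnings

import numpy as np
import pytest

from parseg.exceptions import CurveFitError, GridError
from parseg.size_selection import (
    SizeGrid,
    build_size_grid,
    fit_consistency_curve,
    iterative_size_search,
    select_optimal_size,
    standardize,
)
from parseg.validation import ClassifierSpec

from helpers import make_dataset


class TestBuildSizeGrid:
    def test_full_default_grid(self):
        grid = build_size_grid(318_187)
        assert len(grid) == 28
        assert grid.sizes[0] == 100
        assert grid.n == 318_187
        assert len(set(grid.sizes)) == 28

    def test_clamped_grid(self):
        grid = build_size_grid(1000)
        assert grid.sizes == (100, 150, 200, 300, 400, 500, 700, 1000)

    def test_explicit_grid(self):
        grid = build_size_grid(50, explicit=[20, 10, 50])
        assert grid.sizes == (10, 20, 50)

    def test_explicit_grid_appends_n(self):
        assert build_size_grid(60, explicit=[10, 20]).n == 60

    def test_explicit_entry_above_n_errors(self):
        with pytest.raises(GridError):
            build_size_grid(50, explicit=[10, 80])

    def test_n_below_smallest_default_errors(self):
        with pytest.raises(GridError):
            build_size_grid(50)

    def test_nonincreasing_rejected(self):
        with pytest.raises(GridError):
            SizeGrid((10, 10, 20))


class TestStandardize:
    def test_min_max(self):
        np.testing.assert_allclose(standardize([100, 550, 1000]), [0, 0.5, 1])

    def test_endpoints(self):
        out = standardize([3, 9, 5, 7])
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_vector_errors(self):
        with pytest.raises(CurveFitError):
            standardize([5, 5, 5])


class TestFitConsistencyCurve:
    def test_linear_data_gives_unit_negative_slope(self):
        x = np.linspace(0, 1, 12)
        fit = fit_consistency_curve(x, 1 - x)
        grid = np.linspace(0.05, 0.95, 19)
        np.testing.assert_allclose(fit.derivative(grid), -np.ones_like(grid), atol=1e-8)

    def test_quadratic_derivative_recovered(self):
        x = np.linspace(0, 1, 15)
        fit = fit_consistency_curve(x, (1 - x) ** 2)
        grid = np.linspace(0.1, 0.9, 17)
        np.testing.assert_allclose(fit.derivative(grid), -2 * (1 - grid), atol=0.05)

    def test_four_points_supported_three_rejected(self):
        x = np.array([0, 1 / 3, 2 / 3, 1.0])
        fit = fit_consistency_curve(x, 1 - x)
        assert fit.derivative(0.5) == pytest.approx(-1.0)
        with pytest.raises(CurveFitError):
            fit_consistency_curve(x[:3], (1 - x)[:3])


class TestSelectOptimalSize:
    def test_all_ties_pick_smallest(self):
        x = np.linspace(0, 1, 10)
        fit = fit_consistency_curve(x, 1 - x)
        sizes = [100, 200, 300, 500, 1000, 2000, 3000, 5000, 7000, 10000]
        assert select_optimal_size(fit, sizes, sizes_std=x) == 100

    def test_quadratic_selects_midrange(self):
        sizes = np.arange(100, 1100, 100)
        x = standardize(sizes)
        fit = fit_consistency_curve(x, (1 - x) ** 2)
        # h' = -1 at x = 0.5: the candidate nearest mid-range wins
        got = select_optimal_size(fit, sizes, sizes_std=x)
        assert abs(standardize(sizes)[list(sizes).index(got)] - 0.5) <= 0.06

    def test_convex_curve_interior_selection(self):
        sizes = np.arange(10, 210, 10)
        x = standardize(sizes)
        fit = fit_consistency_curve(x, (1 - x) ** 3)
        got = select_optimal_size(fit, sizes, sizes_std=x)
        assert sizes[0] < got < sizes[-1]


def _search_dataset(seed=5):
    rng = np.random.default_rng(seed)
    n = 1200
    labels = (rng.random(n) < 0.3).astype(np.uint8)
    ds = make_dataset(labels, rng, separation=0.15, noise_sd=0.12)
    return ds, np.arange(n)


class TestIterativeSizeSearch:
    def test_trace_contract_and_caching(self):
        ds, subset = _search_dataset()
        grid = build_size_grid(len(subset), explicit=[50, 80, 120, 180, 260, 380, 550, 800])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            trace = iterative_size_search(
                ds, subset, grid, l=4, gamma=2, B=6, pi=4,
                spec=ClassifierSpec(), rng=np.random.default_rng(0),
            )
        # psi anchor: reference size has psi exactly 0 in every iteration
        for it in trace.iterations:
            assert it.psi[it.candidates.index(grid.n)] == 0.0
            assert it.alpha <= trace.gamma
        # caching: one ReplicateStats per distinct size at most
        assert len(trace.stats) <= len(grid) + 1
        assert trace.s_star in grid.sizes
        assert trace.converged == (trace.iterations[-1].alpha >= trace.gamma)

    def test_determinism(self):
        ds, subset = _search_dataset()
        grid = build_size_grid(len(subset), explicit=[50, 100, 200, 400, 700])
        def run():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return iterative_size_search(
                    ds, subset, grid, l=3, gamma=2, B=5, pi=4,
                    spec=ClassifierSpec(), rng=np.random.default_rng(42),
                )
        t1, t2 = run(), run()
        assert t1.s_star == t2.s_star
        assert [it.s_star for it in t1.iterations] == [it.s_star for it in t2.iterations]
        for s in t1.stats:
            np.testing.assert_array_equal(t1.stats[s].phis, t2.stats[s].phis)

    def test_flat_psi_selects_smallest(self, separable_scene):
        from parseg.pixel_data import build_pixel_dataset

        image, truth = separable_scene
        ds = build_pixel_dataset(image, truth)
        subset = np.arange(ds.n)
        grid = build_size_grid(ds.n, explicit=[60, 90, 140, 210, 320, 480, 720])
        trace = iterative_size_search(
            ds, subset, grid, l=3, gamma=2, B=4, pi=4,
            spec=ClassifierSpec(), rng=np.random.default_rng(1),
        )
        assert trace.converged
        assert trace.s_star == 60
        assert all(it.degenerate_flat for it in trace.iterations)

    def test_exhaustion_warns(self):
        ds, subset = _search_dataset(9)
        grid = build_size_grid(len(subset), explicit=[50, 100, 200, 400, 700])
        with pytest.warns(UserWarning, match="exhausted"):
            trace = iterative_size_search(
                ds, subset, grid, l=4, gamma=50, B=5, pi=4,
                spec=ClassifierSpec(), rng=np.random.default_rng(2),
            )
        assert not trace.converged
        assert trace.s_star is not None

    def test_l_below_three_rejected(self):
        ds, subset = _search_dataset()
        grid = build_size_grid(len(subset), explicit=[50, 100, 200, 400])
        with pytest.raises(GridError):
            iterative_size_search(ds, subset, grid, l=2, gamma=1, B=4, pi=4)

    def test_json_and_csv_export(self, tmp_path):
        ds, subset = _search_dataset()
        grid = build_size_grid(len(subset), explicit=[50, 100, 200, 400, 700])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            trace = iterative_size_search(
                ds, subset, grid, l=3, gamma=1, B=4, pi=4,
                spec=ClassifierSpec(), rng=np.random.default_rng(3),
            )
        trace.to_json(tmp_path / "trace.json")
        table = trace.psi_table()
        assert {"size", "phi_bar", "sigma", "psi"} <= set(table.columns)
        assert (tmp_path / "trace.json").exists()
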