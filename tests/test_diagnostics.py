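import numpy as np
import pytest

from oxymap.diagnostics import (
    RegionMask,
    benchmark_report,
    benchmark_scores,
    change_field,
    compute_diagnostics,
    contemporary_spread_maps,
    contemporary_vs_projected_rank_correlation,
    mask_low_variance,
    noise_to_signal,
    regional_average,
    weighted_moments,
)
from oxymap.pce import SobolField, fit_pce, sobol_decompose


@pytest.fixture(scope="module")
def sobol_2000(archive):
    return sobol_decompose(fit_pce(archive.design, archive.slice(2000).values))


class TestChangeField:
    def test_identical_slices_give_zero(self, archive):
        assert np.all(change_field(archive, 2000, 2000) == 0.0)

    def test_antisymmetric_under_slice_swap(self, archive):
        fwd = change_field(archive, 1850, 2100)
        back = change_field(archive, 2100, 1850)
        np.testing.assert_array_equal(fwd, -back)

    def test_projected_change_nonpositive_in_the_mean(self, archive):
        mean, _ = weighted_moments(change_field(archive), archive.weights)
        assert np.all(mean <= 1e-9)

    def test_missing_slice_raises(self, archive):
        with pytest.raises(KeyError):
            change_field(archive, 1850, 2200)


class TestNoiseToSignal:
    def test_arithmetic(self):
        # two equiprobable runs, one column: mean -10, sd 5 -> 50%
        change = np.array([[-15.0], [-5.0]])
        ns = noise_to_signal(change, None)
        assert ns[0] == pytest.approx(50.0)

    def test_zero_spread_gives_zero(self):
        ns = noise_to_signal(np.full((4, 1), -20.0), None)
        assert ns[0] == pytest.approx(0.0)

    def test_zero_mean_gives_missing_not_infinite(self):
        change = np.array([[1.0], [-1.0]])
        ns = noise_to_signal(change, None)
        assert np.isnan(ns[0])

    def test_cv_equals_noise_to_signal_of_raw_field(self, archive):
        w = archive.weights
        _, cv = contemporary_spread_maps(archive, w)
        ns_raw = noise_to_signal(archive.slice(2000).values, w)
        np.testing.assert_allclose(cv, ns_raw, rtol=1e-12)

    def test_identical_runs_give_zero_spread_and_cv(self, archive):
        field = np.tile(archive.slice(2000).values[:1], (archive.n_runs, 1))
        mean, sd = weighted_moments(field, archive.weights)
        assert sd == pytest.approx(np.zeros_like(sd), abs=1e-9)


class TestLowVarianceMask:
    def make_sobol(self, sd):
        frac = {k: np.full(len(sd), np.nan) for k in
                ("S_w", "S_kappa", "S_a", "S_w_kappa", "S_w_a", "S_kappa_a", "S_w_kappa_a")}
        return SobolField(np.asarray(sd) ** 2, frac)

    def test_six_percent_threshold(self):
        mean = np.array([100.0, 100.0, 100.0])
        sobol = self.make_sobol([5.0, 20.0, 0.0])
        mask = mask_low_variance(sobol, mean, threshold_frac=0.06)
        assert mask.tolist() == [True, False, True]  # 5% masked, 20% kept, zero masked

    def test_ventilated_regime_is_masked_tropics_are_not(self, archive, sobol_2000):
        mean, _ = weighted_moments(archive.slice(2000).values, archive.weights)
        mask = mask_low_variance(sobol_2000, mean)
        regimes = archive.regimes
        assert mask[regimes == "deep_water_formation"].all()
        assert not mask[regimes == "tropical_omz"].any()


class TestRegionalAverage:
    def test_single_column_region_returns_indices_verbatim(self, archive, sobol_2000):
        table = regional_average(sobol_2000, [RegionMask("one", columns=(40,))], archive)
        assert table.loc["one", "S_kappa"] == pytest.approx(sobol_2000.fractions["S_kappa"][40])

    def test_uniform_region_passes_through(self, archive):
        frac = {k: np.full(archive.n_columns, 12.5) for k in
                ("S_w", "S_kappa", "S_a", "S_w_kappa", "S_w_a", "S_kappa_a", "S_w_kappa_a")}
        sobol = SobolField(np.ones(archive.n_columns), frac)
        table = regional_average(sobol, [RegionMask("all", columns=tuple(range(archive.n_columns)))], archive)
        assert table.loc["all", "S_w"] == pytest.approx(12.5)

    def test_partition_recovers_global_mean(self, archive, sobol_2000):
        regimes = archive.regimes
        regions = [RegionMask(r, regime=r) for r in sorted(set(regimes))]
        table = regional_average(sobol_2000, regions, archive)
        sizes = table["n_columns"].values
        for col in ("S_w", "S_kappa", "S_a"):
            pooled = np.nansum(table[col].values * sizes) / sizes.sum()
            direct = np.nanmean(sobol_2000.fractions[col])
            assert pooled == pytest.approx(direct, abs=1e-10)

    def test_pooled_variance_mode_weights_by_local_variance(self, archive, sobol_2000):
        cols = tuple(np.flatnonzero(archive.regimes == "tropical_omz")[:10])
        region = [RegionMask("t", columns=cols)]
        plain = regional_average(sobol_2000, region, archive)
        pooled = regional_average(sobol_2000, region, archive, mode="pooled_variance")
        idx = np.asarray(cols)
        D = sobol_2000.total_variance[idx]
        expected = 100.0 * np.sum(sobol_2000.fractions["S_w"][idx] / 100.0 * D) / D.sum()
        assert pooled.loc["t", "S_w"] == pytest.approx(expected)
        # pooled completeness still holds even though columns differ
        total = sum(pooled.loc["t", c] for c in
                    ("S_w", "S_kappa", "S_a", "S_w_kappa", "S_w_a", "S_kappa_a", "S_w_kappa_a"))
        assert total == pytest.approx(100.0, rel=1e-9)
        assert plain.loc["t", "S_w"] != pooled.loc["t", "S_w"]

    def test_overlapping_regions_rejected(self, archive, sobol_2000):
        regions = [RegionMask("a", columns=(1, 2)), RegionMask("b", columns=(2, 3))]
        with pytest.raises(ValueError):
            regional_average(sobol_2000, regions, archive)

    def test_fully_masked_region_reports_nan(self, archive, sobol_2000):
        mask = np.ones(archive.n_columns, dtype=bool)
        table = regional_average(sobol_2000, [RegionMask("x", columns=(0, 1))], archive, mask)
        assert np.isnan(table.loc["x", "S_w"])

    def test_lat_lon_box_selection(self, archive):
        ds = archive.ds.copy()
        ds["lat"] = ("column", np.linspace(-60, 60, archive.n_columns))
        ds["lon"] = ("column", np.linspace(0, 359, archive.n_columns))
        from oxymap.archive import EnsembleArchive

        arc2 = EnsembleArchive(ds)
        idx = RegionMask("belt", box=(-10, 10, 0, 360)).resolve(arc2)
        lats = ds["lat"].values[idx]
        assert np.all((lats >= -10) & (lats <= 10))
        assert idx.size > 0


class TestBenchmarkScores:
    def test_high_spread_unmasked_column_scores_its_main_effect(self):
        frac = {k: np.zeros(3) for k in
                ("S_w", "S_kappa", "S_a", "S_w_kappa", "S_w_a", "S_kappa_a", "S_w_kappa_a")}
        frac["S_kappa"] = np.array([90.0, 10.0, 50.0])
        sobol = SobolField(np.ones(3), frac)
        spread = np.array([10.0, 1.0, 2.0])
        mask = np.array([False, False, True])
        scores = benchmark_scores(sobol, spread, mask)
        assert scores["kappa"][0] == pytest.approx(90.0)  # above-median spread
        assert np.isnan(scores["kappa"][2])  # masked
        assert np.isnan(scores["kappa"][1])  # below-median spread

    def test_kappa_benchmark_ranking_agrees_with_mc_oracle(self, archive, sobol_2000):
        """The top kappa-benchmark column must have a larger Monte-Carlo
        Sobol kappa main effect (estimated on the actual column solver,
        no PCE involved) than the lowest-scoring eligible column."""
        from oxymap.params import ParameterSet
        from oxymap.toyocean import ColumnGrid, WorldConfig, generate_world, solve_column
        from .oracles import saltelli_sobol

        spread, _ = contemporary_spread_maps(archive, archive.weights)
        mean, _ = weighted_moments(archive.slice(2000).values, archive.weights)
        mask = mask_low_variance(sobol_2000, mean)
        scores = benchmark_scores(sobol_2000, spread, mask)["kappa"]
        eligible = np.flatnonzero(np.isfinite(scores))
        assert eligible.size >= 2
        best_col = eligible[np.argmax(scores[eligible])]
        worst_col = eligible[np.argmin(scores[eligible])]
        assert scores[best_col] - scores[worst_col] > 3.0  # a real contrast to rank

        ps = ParameterSet.default()
        world = generate_world(WorldConfig(), seed=0)
        grid = ColumnGrid()
        rng = np.random.default_rng(42)
        mc = {}
        for col_idx in (int(best_col), int(worst_col)):
            col = world[col_idx]

            def f(x):
                out = np.empty(x.shape[0])
                for i, xi in enumerate(x):
                    w, k, a = ps.destandardize(xi)
                    out[i] = solve_column(col, grid, w, k, a, 2000).min_o2
                return out

            est, se = saltelli_sobol(f, 800, rng, n_blocks=4)
            mc[col_idx] = (est["S_kappa"], se["S_kappa"])
        gap = mc[int(best_col)][0] - mc[int(worst_col)][0]
        noise = 3 * np.hypot(mc[int(best_col)][1], mc[int(worst_col)][1])
        assert gap > -noise  # oracle confirms the ordering (up to MC error)


def test_rank_correlation_is_finite_and_below_one(archive, sobol_2000):
    maps = compute_diagnostics(archive, sobol_2000)
    assert np.isfinite(maps.rank_correlation)
    assert maps.rank_correlation < 1.0


def test_rank_correlation_degenerate_input():
    assert np.isnan(contemporary_vs_projected_rank_correlation(np.array([1.0]), np.array([2.0])))
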