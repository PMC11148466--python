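import numpy as np
import pytest
from scipy.stats import ks_2samp

from infosurr import (
    ARSpec,
    EmbeddingSpec,
    SurrogateSpec,
    TimeSeries,
    VARSpec,
    build_bivariate_observation,
    build_univariate_observation,
    estimate_is,
    estimate_mir,
    iaaft,
    iaaft_bivariate,
    shuffle_present,
    shuffle_rows_block,
    simulate_ar2,
    simulate_var2,
    zscore_normalize,
)
from infosurr.embedding import ObservationMatrix


@pytest.fixture(scope="module")
def ar_series():
    return zscore_normalize(simulate_ar2(ARSpec(rho=0.8, n=500), np.random.default_rng(0)))


@pytest.fixture(scope="module")
def var_pair():
    x, y = simulate_var2(VARSpec(C=1.0, n=500), np.random.default_rng(1))
    return zscore_normalize(x), zscore_normalize(y)


class TestShufflePresent:
    def test_multiset_and_past_columns_preserved(self, ar_series):
        obs = build_univariate_observation(ar_series, EmbeddingSpec())
        surr = shuffle_present(obs, np.random.default_rng(2))
        np.testing.assert_array_equal(np.sort(surr.data[:, 0]), np.sort(obs.data[:, 0]))
        np.testing.assert_array_equal(surr.data[:, 1:], obs.data[:, 1:])
        assert not np.array_equal(surr.data[:, 0], obs.data[:, 0])

    def test_single_row_identity(self):
        obs = build_univariate_observation(TimeSeries([1.0, 2.0, 3.0]), EmbeddingSpec(q=2, k=1))
        surr = shuffle_present(obs, np.random.default_rng(0))
        np.testing.assert_array_equal(surr.data, obs.data)

    def test_seeded_reproducibility(self, ar_series):
        obs = build_univariate_observation(ar_series, EmbeddingSpec())
        a = shuffle_present(obs, np.random.default_rng(7)).data
        b = shuffle_present(obs, np.random.default_rng(7)).data
        c = shuffle_present(obs, np.random.default_rng(8)).data
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_rejects_bivariate(self, var_pair):
        obs = build_bivariate_observation(*var_pair, EmbeddingSpec())
        with pytest.raises(ValueError):
            shuffle_present(obs, np.random.default_rng(0))


class TestShuffleRowsBlock:
    def test_row_set_conserved_other_block_untouched(self, var_pair):
        obs = build_bivariate_observation(*var_pair, EmbeddingSpec())
        surr = shuffle_rows_block(obs, np.random.default_rng(3))
        bx0, bx1 = obs.block("x"), surr.block("x")
        np.testing.assert_array_equal(
            bx0[np.lexsort(bx0.T)], bx1[np.lexsort(bx1.T)]
        )
        np.testing.assert_array_equal(surr.block("y"), obs.block("y"))

    def test_block_is_estimated_as_point_set(self, var_pair):
        """IS depends only on the set of embedded rows, so shuffling the
        block rows leaves the block's IS bit-identical."""
        obs = build_bivariate_observation(*var_pair, EmbeddingSpec())
        surr = shuffle_rows_block(obs, np.random.default_rng(4))

        def as_univ(block_data):
            roles = tuple(("x", l) for l in range(block_data.shape[1]))
            return ObservationMatrix(block_data, roles, ("x",), obs.q)

        assert estimate_is(as_univ(obs.block("x"))).value == estimate_is(as_univ(surr.block("x"))).value

    def test_block_choice_statistically_equivalent(self, var_pair):
        """Shuffling the X block or the Y block yields indistinguishable
        surrogate MIR distributions (two-sample KS on 60 surrogates each)."""
        obs = build_bivariate_observation(*var_pair, EmbeddingSpec())
        vx = [
            estimate_mir(shuffle_rows_block(obs, np.random.default_rng(100 + i), block="x")).value
            for i in range(60)
        ]
        vy = [
            estimate_mir(shuffle_rows_block(obs, np.random.default_rng(500 + i), block="y")).value
            for i in range(60)
        ]
        assert ks_2samp(vx, vy).pvalue > 0.005

    def test_invalid_selector(self, var_pair):
        obs = build_bivariate_observation(*var_pair, EmbeddingSpec())
        with pytest.raises(ValueError, match="unknown block"):
            shuffle_rows_block(obs, np.random.default_rng(0), block="z")


def _rel_spectral_rmse(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.abs(np.fft.rfft(a)), np.abs(np.fft.rfft(b))
    return float(np.sqrt(np.mean((sa - sb) ** 2)) / np.sqrt(np.mean(sa**2)))


class TestIaaft:
    def test_multiset_preserved_exactly(self, ar_series):
        surr = iaaft(ar_series, 7, np.random.default_rng(0))
        np.testing.assert_array_equal(np.sort(surr.values), np.sort(ar_series.values))

    def test_spectrum_approximated(self, ar_series):
        worst = max(
            _rel_spectral_rmse(ar_series.values, iaaft(ar_series, 7, np.random.default_rng(s)).values)
            for s in range(5)
        )
        assert worst < 0.05

    def test_spectral_discrepancy_not_worse_than_start(self, ar_series):
        rng = np.random.default_rng(9)
        start = rng.permutation(ar_series.values)
        rng2 = np.random.default_rng(9)
        out = iaaft(ar_series, 7, rng2)
        assert _rel_spectral_rmse(ar_series.values, out.values) <= _rel_spectral_rmse(
            ar_series.values, start
        )

    def test_sinusoid_dominant_frequency_preserved(self):
        t = np.arange(512)
        sin = TimeSeries(np.sin(2 * np.pi * 0.1 * t))
        surr = iaaft(sin, 7, np.random.default_rng(0))
        assert np.argmax(np.abs(np.fft.rfft(surr.values))) == np.argmax(
            np.abs(np.fft.rfft(sin.values))
        )

    def test_constant_series_warns_and_passes_through(self):
        with pytest.warns(UserWarning, match="constant"):
            out = iaaft(TimeSeries(np.ones(32)), 7, np.random.default_rng(0))
        np.testing.assert_array_equal(out.values, np.ones(32))

    def test_seeded_reproducibility(self, ar_series):
        a = iaaft(ar_series, 7, np.random.default_rng(5)).values
        b = iaaft(ar_series, 7, np.random.default_rng(5)).values
        np.testing.assert_array_equal(a, b)

    def test_too_short(self):
        with pytest.raises(ValueError):
            iaaft(TimeSeries(np.arange(5.0)), 7, np.random.default_rng(0))


class TestIaaftBivariate:
    def test_multisets_preserved(self, var_pair):
        sx, sy = iaaft_bivariate(*var_pair, 7, np.random.default_rng(0))
        np.testing.assert_array_equal(np.sort(sx.values), np.sort(var_pair[0].values))
        np.testing.assert_array_equal(np.sort(sy.values), np.sort(var_pair[1].values))

    def test_identical_inputs_give_identical_outputs(self, ar_series):
        x2 = TimeSeries(ar_series.values.copy(), label="x2")
        sx, sy = iaaft_bivariate(ar_series, x2, 7, np.random.default_rng(1))
        np.testing.assert_array_equal(sx.values, sy.values)

    def test_cross_correlation_preserved(self, var_pair):
        """Common-phase randomization keeps the cross-spectrum, so the mean
        surrogate cross-correlogram matches the original."""
        x, y = var_pair

        def ccf(a, b, lags=6):
            a = (a - a.mean()) / a.std()
            b = (b - b.mean()) / b.std()
            n = a.size
            return np.array([np.mean(a[: n - l] * b[l:]) for l in range(lags + 1)])

        c0 = ccf(x.values, y.values)
        cs = np.mean(
            [
                ccf(*(s.values for s in iaaft_bivariate(x, y, 7, np.random.default_rng(s))))
                for s in range(60)
            ],
            axis=0,
        )
        assert np.max(np.abs(c0 - cs)) < 0.05

    def test_length_mismatch(self, ar_series):
        with pytest.raises(ValueError):
            iaaft_bivariate(ar_series, TimeSeries(np.arange(10.0)), 7, np.random.default_rng(0))

    def test_seeded_reproducibility(self, var_pair):
        a = iaaft_bivariate(*var_pair, 7, np.random.default_rng(5))
        b = iaaft_bivariate(*var_pair, 7, np.random.default_rng(5))
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[1].values, b[1].values)


class TestSurrogateSpec:
    def test_too_few_surrogates(self):
        with pytest.raises(ValueError):
            SurrogateSpec("iaaft", n_surrogates=10)

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown surrogate method"):
            SurrogateSpec("twin", n_surrogates=100)

    def test_zero_iterations(self):
        with pytest.raises(ValueError):
            SurrogateSpec("iaaft", n_surrogates=100, iterations=0)
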