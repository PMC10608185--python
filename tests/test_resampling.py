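import numpy as np
import pytest
from scipy import stats

from hoconn.io_core import (
    DegenerateChannelError,
    Multiplet,
    ResamplingConfig,
    ValidationError,
    spawn_rng,
)
from hoconn.resampling import (
    BootstrapEnsemble,
    MeasureSpec,
    block_bootstrap,
    bootstrap_distribution,
    condition_difference,
    iaaft_surrogate,
    increment_significance,
    mi_significance,
    oi_zero_significance,
    percentile,
)
from hoconn.simulator import simulate_gaussian

from conftest import make_ts


def sort_index_percentile(values, q):
    """From-scratch percentile oracle: sort + linear interpolation."""
    v = np.sort(np.asarray(values, dtype=float))
    pos = (q / 100.0) * (v.size - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return v[lo] + (pos - lo) * (v[hi] - v[lo])


def ar1(m, phi, seed):
    rng = spawn_rng(seed, "ar1")
    x = np.zeros(m)
    e = rng.standard_normal(m)
    for t in range(1, m):
        x[t] = phi * x[t - 1] + e[t]
    return x


class TestPercentile:
    @pytest.mark.parametrize("q", [2.5, 5.0, 50.0, 95.0, 97.5])
    def test_matches_sort_oracle(self, rng, q):
        values = rng.standard_normal(301)
        assert percentile(values, q) == pytest.approx(
            sort_index_percentile(values, q), abs=1e-12)


class TestIaaft:
    def test_amplitude_multiset_exact(self, rng):
        x = rng.exponential(size=200)  # deliberately non-Gaussian amplitudes
        s = iaaft_surrogate(x, seed=4)
        assert np.array_equal(np.sort(s), np.sort(x))

    def test_white_noise_moments_and_reordering(self, rng):
        x = rng.standard_normal(300)
        s = iaaft_surrogate(x, seed=8)
        assert not np.array_equal(s, x)
        assert s.mean() == pytest.approx(x.mean(), abs=1e-12)
        assert s.std() == pytest.approx(x.std(), abs=1e-12)

    def test_autocorrelated_spectrum_matched(self):
        x = ar1(512, 0.9, seed=12)
        s = iaaft_surrogate(x, seed=3, max_iter=100, tol=0.01)
        amp_x = np.abs(np.fft.rfft(x))
        amp_s = np.abs(np.fft.rfft(s))
        rel_err = np.linalg.norm(amp_s - amp_x) / np.linalg.norm(amp_x)
        assert rel_err < 0.01

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateChannelError):
            iaaft_surrogate(np.full(64, 3.0), seed=0)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            iaaft_surrogate(np.arange(5.0), seed=0)

    def test_deterministic_under_seed(self, rng):
        x = rng.standard_normal(128)
        assert np.array_equal(iaaft_surrogate(x, seed=5),
                              iaaft_surrogate(x, seed=5))


class TestMiSignificance:
    def test_strong_coupling_significant(self):
        rng = spawn_rng(1, "coupled")
        x = rng.standard_normal(500)
        y = 0.99 * x + 0.1 * rng.standard_normal(500)
        ts = make_ts(np.column_stack([x, y]))
        est = mi_significance(ts, 0, 1, ResamplingConfig(seed=2))
        assert est.significant is True
        assert est.value > est.threshold

    def test_independent_usually_nonsignificant(self):
        rng = spawn_rng(2, "uncoupled")
        ts = make_ts(rng.standard_normal((500, 2)))
        est = mi_significance(ts, 0, 1,
                              ResamplingConfig(seed=3, n_surrogates=100))
        assert est.threshold > 0.0

    def test_self_pair_rejected(self, random_ts):
        with pytest.raises(ValidationError):
            mi_significance(random_ts, 1, 1, ResamplingConfig(seed=0))

    def test_accepts_labels(self, random_ts):
        est = mi_significance(random_ts, "S1", "S2",
                              ResamplingConfig(seed=0, n_surrogates=20))
        assert est.threshold is not None


class TestBlockBootstrap:
    def test_full_length_block_is_identity(self, random_ts):
        cfg = ResamplingConfig(seed=1, block_length=random_ts.n_samples)
        boot = block_bootstrap(random_ts, cfg)
        assert np.array_equal(boot.data, random_ts.data)

    def test_block_structure(self):
        rng = spawn_rng(4, "blocks")
        ts = make_ts(rng.standard_normal((200, 3)))
        cfg = ResamplingConfig(seed=5, block_length=50)
        boot = block_bootstrap(ts, cfg)
        assert boot.n_samples == 200
        originals = [ts.data[k * 50:(k + 1) * 50] for k in range(4)]
        for c in range(4):
            chunk = boot.data[c * 50:(c + 1) * 50]
            assert any(np.array_equal(chunk, block) for block in originals)

    def test_resampling_closure(self, random_ts):
        cfg = ResamplingConfig(seed=9, block_length=25)
        boot = block_bootstrap(random_ts, cfg)
        for c in range(random_ts.n_channels):
            assert np.all(np.isin(boot.data[:, c], random_ts.data[:, c]))

    def test_block_longer_than_series(self, random_ts):
        cfg = ResamplingConfig(seed=0, block_length=random_ts.n_samples + 1)
        with pytest.raises(ValidationError):
            block_bootstrap(random_ts, cfg)


class TestBootstrapDistribution:
    def test_coupled_pair_all_finite(self):
        cov = np.array([[1.0, 0.7], [0.7, 1.0]])
        ts = simulate_gaussian(cov, 200, seed=6)
        cfg = ResamplingConfig(seed=7, n_bootstrap=300, block_length=50)
        ens = bootstrap_distribution(ts, MeasureSpec.mi(0, 1), cfg)
        assert ens.measure_values.size == 300
        assert np.all(np.isfinite(ens.measure_values))
        assert ens.n_skipped == 0

    def test_pair_oi_identically_zero(self, random_ts):
        cfg = ResamplingConfig(seed=8, n_bootstrap=300, block_length=50)
        ens = bootstrap_distribution(random_ts, MeasureSpec.oi((0, 1)), cfg)
        assert np.all(ens.measure_values == 0.0)

    def test_ci_matches_percentile_oracle(self, random_ts):
        cfg = ResamplingConfig(seed=10, n_bootstrap=200, block_length=50,
                               alpha=0.05)
        ens = bootstrap_distribution(random_ts, MeasureSpec.oi((0, 1, 2)), cfg)
        assert ens.ci[0] == pytest.approx(
            sort_index_percentile(ens.measure_values, 2.5), abs=1e-12)
        assert ens.ci[1] == pytest.approx(
            sort_index_percentile(ens.measure_values, 97.5), abs=1e-12)

    def test_bit_reproducible(self, random_ts):
        cfg = ResamplingConfig(seed=11, n_bootstrap=100, block_length=40)
        spec = MeasureSpec.oi((1, 3, 5))
        a = bootstrap_distribution(random_ts, spec, cfg)
        b = bootstrap_distribution(random_ts, spec, cfg)
        assert np.array_equal(a.measure_values, b.measure_values)
        assert a.ci == b.ci

    def test_doi_measure(self, random_ts):
        cfg = ResamplingConfig(seed=12, n_bootstrap=50, block_length=50)
        ens = bootstrap_distribution(
            random_ts, MeasureSpec.doi((0, 1, 2), 2), cfg)
        assert ens.measure_values.size == 50
        assert ens.measure_id == "doi:0-1-2>2"


def _ens(values, measure_id="oi:0-1-2", alpha=0.05):
    values = np.asarray(values, dtype=float)
    return BootstrapEnsemble(
        measure_values=values,
        ci=(percentile(values, 100 * alpha / 2),
            percentile(values, 100 * (1 - alpha / 2))),
        measure_id=measure_id)


class TestOiZeroSignificance:
    def test_all_positive_significant(self, rng):
        ens = _ens(rng.random(300) + 0.1)
        assert oi_zero_significance(ens, 0.05) is True

    def test_symmetric_about_zero_not_significant(self, rng):
        ens = _ens(rng.standard_normal(300))
        assert oi_zero_significance(ens, 0.05) is False

    def test_boundary_matches_percentile_oracle(self, rng):
        values = rng.standard_normal(300) + 1.5
        ens = _ens(values)
        lo = sort_index_percentile(values, 2.5)
        hi = sort_index_percentile(values, 97.5)
        assert oi_zero_significance(ens, 0.05) == (not lo < 0.0 < hi)

    def test_degenerate_zero_distribution_not_significant(self):
        ens = _ens(np.zeros(300))
        assert oi_zero_significance(ens, 0.05) is False


class TestIncrementSignificance:
    def test_identical_distributions_not_significant(self, rng):
        v = rng.standard_normal(300)
        assert increment_significance(_ens(v), _ens(v.copy()), 0.05) is False

    def test_extreme_shift_significant(self, rng):
        v = rng.standard_normal(300)
        shifted = v + 10 * v.std()
        assert increment_significance(_ens(shifted), _ens(v), 0.05) is True

    def test_pvalue_matches_textbook_t(self, rng):
        a = rng.standard_normal(300) + 0.05
        b = rng.standard_normal(300)
        # textbook pooled-variance unpaired t computation
        na, nb = a.size, b.size
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p = 2 * stats.t.sf(abs(t), na + nb - 2)
        expected = p < 0.05
        assert increment_significance(_ens(a), _ens(b), 0.05) == expected
        # and the decision flips at alpha just around p
        assert increment_significance(_ens(a), _ens(b), min(p * 1.01, 0.999)) is True
        assert increment_significance(_ens(a), _ens(b), p * 0.99) is False


class TestConditionDifference:
    def test_self_comparison_no_difference(self, rng):
        v = rng.standard_normal(300)
        d = condition_difference(_ens(v), _ens(v.copy()), 0.05)
        assert d.decision == "no difference"
        assert d.delta == 0.0

    def test_constructed_effect_higher(self, rng):
        a = rng.standard_normal(300)
        b = a + 1.0
        d = condition_difference(_ens(a), _ens(b), 0.05)
        assert d.decision == "higher"
        assert d.delta == pytest.approx(1.0, abs=1e-12)

    def test_sign_convention_lower(self, rng):
        a = rng.standard_normal(300) + 2.0
        b = rng.standard_normal(300)
        d = condition_difference(_ens(a), _ens(b), 0.05)
        assert d.decision == "lower"
        assert d.delta < 0

    def test_measure_mismatch_rejected(self, rng):
        a = _ens(rng.standard_normal(10), measure_id="mi:0|1")
        b = _ens(rng.standard_normal(10), measure_id="mi:0|2")
        with pytest.raises(ValidationError):
            condition_difference(a, b, 0.05)
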