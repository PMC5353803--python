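"""Length normalization, d-scores, genus statistics, r-scores and the ECDF."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microtax.uncertainty import (
    GenusScoreStats,
    LengthNormModel,
    d_score,
    fit_genus_stats,
    fit_length_norm_pairs,
    loess_smooth,
    normalize_logprob,
    r_probability,
    r_score,
    shrink_sd,
)

NORM = LengthNormModel(mean_coef=(-10.0, -1.0), sd_coef=(1.0, 0.01), fit_range=(100, 1500))


class TestNormalize:
    def test_worked_example(self):
        # p_hat(100) = -110, s_hat(100) = 2
        assert normalize_logprob(-120.0, 100, NORM) == pytest.approx(-5.0)

    def test_centred_and_unit_cases(self):
        p_hat = NORM.predict_mean(200)
        s_hat = NORM.predict_sd(200)
        assert normalize_logprob(p_hat, 200, NORM) == pytest.approx(0.0)
        assert normalize_logprob(p_hat + s_hat, 200, NORM) == pytest.approx(1.0)

    def test_extrapolation_warns(self):
        with pytest.warns(UserWarning, match="outside the fitted range"):
            normalize_logprob(-50.0, 50, NORM)

    def test_negative_sd_is_error(self):
        bad = LengthNormModel((-10, -1), (1.0, -0.1), (100, 1500))
        with pytest.raises(ValueError, match="non-positive"):
            normalize_logprob(-50.0, 200, bad, warn_extrapolate=False)


class TestDScore:
    def test_subtraction_and_boundary(self):
        assert d_score(2.0, 0.5) == pytest.approx(1.5)
        assert d_score(1.3, 1.3) == 0.0

    def test_affine_invariance(self):
        """Adding a constant to both raw scores at one length leaves d unchanged."""
        length = 400
        p1, p2, shift = -300.0, -310.0, 57.3
        d0 = d_score(
            normalize_logprob(p1, length, NORM), normalize_logprob(p2, length, NORM)
        )
        d1 = d_score(
            normalize_logprob(p1 + shift, length, NORM),
            normalize_logprob(p2 + shift, length, NORM),
        )
        assert d0 == pytest.approx(d1)


class TestFitLengthNorm:
    def test_parameter_recovery(self, rng):
        """Mean and SD lines are recovered from simulated (length, p1) data."""
        a, b, c, d = -30.0, -9.5, 1.0, 0.004
        lengths = rng.integers(100, 1501, size=5000).astype(float)
        p1 = a + b * lengths + rng.normal(0.0, c + d * lengths)
        m = fit_length_norm_pairs(lengths, p1)
        assert m.mean_coef[0] == pytest.approx(a, rel=0.05)
        assert m.mean_coef[1] == pytest.approx(b, rel=0.05)
        assert m.sd_coef[0] == pytest.approx(c, rel=0.15)
        assert m.sd_coef[1] == pytest.approx(d, rel=0.15)

    def test_too_few_fragments_rejected(self, rng):
        lengths = rng.integers(100, 1501, size=50).astype(float)
        with pytest.raises(ValueError, match="at least 100"):
            fit_length_norm_pairs(lengths, -9.5 * lengths)

    def test_single_length_degenerate(self, rng):
        lengths = np.full(500, 300.0)
        with pytest.raises(ValueError, match="degenerate"):
            fit_length_norm_pairs(lengths, rng.normal(size=500))


class TestShrunkSD:
    def test_singleton_gets_size_estimate_exactly(self):
        assert shrink_sd(np.nan, 2.0, 1) == pytest.approx(2.0)

    def test_worked_example_n2(self):
        assert shrink_sd(1.0, 2.0, 2) == pytest.approx(np.sqrt(2.5))

    def test_large_n_limit(self):
        assert shrink_sd(1.0, 2.0, 10_000) == pytest.approx(1.00015, abs=1e-4)

    def test_matching_sds_fixed_point(self):
        for n in (2, 5, 100):
            assert shrink_sd(1.7, 1.7, n) == pytest.approx(1.7)


class TestLoess:
    def test_quadratic_is_fit_exactly(self):
        x = np.arange(1.0, 21.0)
        y = 0.5 + 0.3 * x - 0.01 * x**2
        np.testing.assert_allclose(loess_smooth(x, y, span=0.75, degree=2), y, atol=1e-8)

    def test_smooths_noise_toward_trend(self, rng):
        x = np.arange(1.0, 41.0)
        y = 1.0 + 0.1 * x + rng.normal(0, 0.5, size=40)
        fit = loess_smooth(x, y)
        assert np.abs(fit - (1.0 + 0.1 * x)).mean() < np.abs(y - (1.0 + 0.1 * x)).mean()


def _toy_stats(ecdf, mean=0.0, sd=1.0):
    return GenusScoreStats(
        genera=["g"],
        sizes=np.array([len(ecdf)]),
        mean=np.array([mean]),
        raw_sd=np.array([sd]),
        size_sd=np.array([sd]),
        shrunk_sd=np.array([sd]),
        ecdf=np.sort(np.asarray(ecdf, dtype=float)),
    )


class TestGenusStats:
    def test_fit_reproduces_group_moments(self, rng):
        labels = [f"g{i}" for i in range(30) for _ in range(12)]
        sigmas = rng.uniform(0.5, 1.5, size=30)
        p = np.concatenate(
            [rng.normal(i * 0.1, sigmas[i], size=12) for i in range(30)]
        )
        stats = fit_genus_stats(p, labels)
        i = stats.genera.index("g3")
        sel = np.asarray(labels) == "g3"
        assert stats.mean[i] == pytest.approx(p[sel].mean())
        assert stats.raw_sd[i] == pytest.approx(p[sel].std(ddof=1))
        assert stats.sizes[i] == 12

    def test_training_r_scores_are_standardized(self, rng):
        """Per-genus training r-scores have mean 0 and SD within [0.5, 1.5]."""
        labels = [f"g{i}" for i in range(30) for _ in range(12)]
        p = np.concatenate(
            [rng.normal(i * 0.1, rng.uniform(0.5, 1.5), size=12) for i in range(30)]
        )
        stats = fit_genus_stats(p, labels)
        for g in stats.genera:
            r = r_score(p[np.asarray(labels) == g], g, stats)
            assert abs(r.mean()) < 0.1
            assert 0.5 <= r.std(ddof=1) <= 1.5

    def test_singleton_genus_uses_size_smoothed_sd(self, rng):
        labels = ["solo"] + ["a"] * 10 + ["b"] * 10
        p = np.concatenate([[0.0], rng.normal(0, 1, 10), rng.normal(0, 1, 10)])
        stats = fit_genus_stats(p, labels)
        i = stats.genera.index("solo")
        assert np.isnan(stats.raw_sd[i])
        assert stats.shrunk_sd[i] == pytest.approx(stats.size_sd[i])

    def test_all_singletons_rejected(self):
        with pytest.raises(ValueError, match="singleton"):
            fit_genus_stats(np.array([0.1, 0.2, 0.3]), ["a", "b", "c"])


class TestRScore:
    def test_centre_and_two_sigma(self):
        stats = _toy_stats([-1, 0, 1], mean=-2.0, sd=0.5)
        assert r_score(-2.0, "g", stats) == pytest.approx(0.0)
        assert r_score(-3.0, "g", stats) == pytest.approx(-2.0)

    def test_unknown_genus_rejected(self):
        with pytest.raises(KeyError):
            r_score(0.0, "nope", _toy_stats([0.0, 1.0]))


class TestRProbability:
    def test_worked_example(self):
        stats = _toy_stats([-3, -1, 0, 2])
        assert r_probability(-1.0, stats) == pytest.approx(2 / 5)

    def test_training_maximum(self):
        stats = _toy_stats([-3, -1, 0, 2])
        assert r_probability(2.0, stats) == pytest.approx(4 / 5)

    def test_floor_below_training_minimum(self):
        stats = _toy_stats([-3, -1, 0, 2])
        assert r_probability(-50.0, stats) == pytest.approx(1 / 5)

    @given(
        st.lists(st.floats(-10, 10), min_size=5, max_size=50),
        st.floats(-15, 15),
        st.floats(0, 5),
    )
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_r(self, train, r, delta):
        stats = _toy_stats(train)
        assert r_probability(r, stats) <= r_probability(r + delta, stats)
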