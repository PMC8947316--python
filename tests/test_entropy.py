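import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from somnentropy import (
    EntropyParams,
    apen,
    cond_entropy,
    disten,
    entropy_features,
    fuzzyen,
    permen,
    sampen,
)

import _oracles


class TestHandComputedValues:
    def test_sampen_of_perfect_alternation_is_zero(self):
        # Psi(2) = Psi(3) = 0.4 by direct enumeration -> -ln(1) = 0
        x = np.array([1, 2, 1, 2, 1, 2, 1, 2], float)
        assert sampen(x) == pytest.approx(0.0, abs=1e-12)

    def test_permen_hand_enumeration(self):
        # ordinal patterns of [4,7,9,10,6,11,3]: counts {2,2,1} over 5 windows
        x = np.array([4, 7, 9, 10, 6, 11, 3], float)
        expected = -(2 * 0.4 * math.log2(0.4) + 0.2 * math.log2(0.2)) / math.log2(6)
        assert permen(x) == pytest.approx(expected, abs=1e-12)
        assert permen(x) == pytest.approx(0.5887, abs=1e-4)

    def test_fuzzyen_of_alternation_near_zero(self):
        x = np.tile([1.0, 2.0], 32)
        assert fuzzyen(x) < 0.05

    def test_ce_of_two_symbol_alternation(self):
        # quantized pattern counts: pairs {(0,5):4,(5,0):3}, triples 3+3,
        # no singleton patterns -> CE = SE(z) - SE(w)
        x = np.array([0, 1, 0, 1, 0, 1, 0, 1], float)
        se_w = math.log(7) - (4 * math.log(4) + 3 * math.log(3)) / 7
        expected = math.log(2) - se_w
        assert cond_entropy(x) == pytest.approx(expected, abs=1e-12)


class TestDegenerateInputs:
    def test_constant_series(self):
        x = np.full(60, 0.8)
        feats = entropy_features(x)
        assert math.isnan(feats.apen) and math.isnan(feats.sampen)
        assert math.isnan(feats.fuzzyen)
        assert feats.flags["sampen"] == "degenerate_tolerance"
        assert feats.disten == 0.0
        assert feats.ce == 0.0
        assert feats.permen == 0.0

    def test_strict_ramp_sampen_has_no_matches(self):
        # short ramp: r = 0.2*sigma ~ 0.7 steps, below the unit step size
        x = np.arange(12.0)
        assert math.isnan(sampen(x))

    def test_fuzzyen_finite_where_sampen_is_not(self):
        x = np.arange(12.0)
        assert math.isfinite(fuzzyen(x))

    def test_monotone_series_permen_zero(self):
        assert permen(np.arange(10.0)) == pytest.approx(0.0)

    def test_series_too_short_raises(self):
        with pytest.raises(ValueError):
            permen(np.array([1.0, 2.0]))


class TestOracleEquivalence:
    """Vectorized estimators against naive loop-based enumeration."""

    @pytest.mark.parametrize(
        "fast,naive",
        [
            (apen, _oracles.apen_naive),
            (sampen, _oracles.sampen_naive),
            (fuzzyen, _oracles.fuzzyen_naive),
            (disten, _oracles.disten_naive),
            (cond_entropy, _oracles.ce_naive),
        ],
    )
    def test_m2_estimators_match_naive(self, fast, naive):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            x = 0.9 + 0.05 * rng.standard_normal(100)
            expected = naive(x)
            if math.isnan(expected):
                assert math.isnan(fast(x))
            else:
                assert fast(x) == pytest.approx(expected, abs=1e-10)

    def test_permen_matches_naive_including_ties(self):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            x = rng.integers(0, 5, size=100).astype(float)  # many ties
            assert permen(x) == pytest.approx(_oracles.permen_naive(x), abs=1e-10)

    def test_logistic_map_disten_matches_histogram_oracle(self):
        x = [0.1]
        for _ in range(19):
            x.append(4.0 * x[-1] * (1.0 - x[-1]))
        x = np.array(x)
        assert disten(x) == pytest.approx(_oracles.disten_naive(x), abs=1e-10)


class TestAsymptotics:
    def test_sampen_iid_gaussian_matches_conditional_match_probability(self):
        from scipy.stats import norm

        expected = -math.log(2 * norm.cdf(0.2 / math.sqrt(2)) - 1)
        x = np.random.default_rng(1).standard_normal(4000)
        assert sampen(x) == pytest.approx(expected, abs=0.1)

    def test_apen_iid_gaussian_tracks_sampen_with_known_bias(self):
        # ApEn's log-of-count averaging biases it low by ~0.12 at N = 4000;
        # it should sit just below the SampEn value, not match it.
        x = np.random.default_rng(1).standard_normal(4000)
        assert sampen(x) - 0.25 < apen(x) < sampen(x)

    def test_permen_iid_noise_saturates(self):
        x = np.random.default_rng(2).standard_normal(5000)
        assert permen(x) == pytest.approx(1.0, abs=0.02)

    def test_ce_iid_uniform_approaches_quantizer_entropy(self):
        x = np.random.default_rng(3).random(2000)
        assert cond_entropy(x) == pytest.approx(math.log(6), abs=0.1)


class TestInvariances:
    def test_irregularity_ordering_noise_ar_sinusoid(self):
        n = 1000
        orderings = {f: [] for f in (sampen, fuzzyen, apen)}
        for seed in range(20):
            rng = np.random.default_rng(seed)
            iid = rng.standard_normal(n)
            ar = np.empty(n)
            ar[0] = rng.standard_normal()
            for i in range(1, n):
                ar[i] = 0.9 * ar[i - 1] + math.sqrt(1 - 0.81) * rng.standard_normal()
            t = np.arange(n)
            sine = np.sin(2 * np.pi * 0.03 * t) + 1e-3 * rng.standard_normal(n)
            for f in orderings:
                orderings[f].append((f(iid), f(ar), f(sine)))
        for f, vals in orderings.items():
            m_iid, m_ar, m_sine = np.mean(vals, axis=0)
            assert m_iid > m_ar > m_sine, f.__name__

    @pytest.mark.parametrize("f", [apen, sampen, fuzzyen])
    def test_affine_scale_invariance(self, f):
        x = 0.9 + 0.05 * np.random.default_rng(5).standard_normal(200)
        assert f(3.7 * x + 11.0) == pytest.approx(f(x), abs=1e-10)

    def test_permen_invariant_under_monotone_transform(self):
        x = np.random.default_rng(6).random(300)
        assert permen(np.exp(5 * x)) == pytest.approx(permen(x), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_disten_and_permen_normalized(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(rng.integers(20, 120))
        assert 0.0 <= disten(x) <= 1.0
        assert 0.0 <= permen(x) <= 1.0

    def test_deterministic(self):
        x = np.random.default_rng(7).standard_normal(150)
        a, b = entropy_features(x), entropy_features(x)
        assert a.as_dict() == b.as_dict()


class TestParams:
    def test_default_parameters(self):
        p = EntropyParams()
        assert (p.m, p.tau, p.r_coeff, p.n_bins, p.xi, p.m_perm) == (2, 1, 0.2, 64, 6, 3)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            EntropyParams(m=0)
        with pytest.raises(ValueError):
            EntropyParams(xi=1)


class TestCompositeConsistency:
    def test_entropy_features_equals_standalone_functions(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = 0.9 + 0.04 * rng.standard_normal(300)
            feats = entropy_features(x)
            assert feats.apen == pytest.approx(apen(x), abs=1e-12)
            assert feats.sampen == pytest.approx(sampen(x), abs=1e-12)
            assert feats.fuzzyen == pytest.approx(fuzzyen(x), abs=1e-12)
            assert feats.disten == pytest.approx(disten(x), abs=1e-12)
            assert feats.ce == pytest.approx(cond_entropy(x), abs=1e-12)
            assert feats.permen == pytest.approx(permen(x), abs=1e-12)
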