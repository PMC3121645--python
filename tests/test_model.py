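"""Transforms, mean models, HWE proportions and parameter counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from tetracall import (
    DOSAGES,
    DomainError,
    MeanModelParams,
    asr_inverse,
    asr_transform,
    compute_ratio_and_intensity,
    hwe_proportions,
    mean_model_eval,
    parameter_count,
)


class TestAsrTransform:
    @pytest.mark.parametrize(
        "ratio, expected, decimals",
        [
            (0.02, 0.142, 3),
            (0.98, 1.429, 3),
            (0.5, np.pi / 4, 10),
            (0.0, 0.0, 12),
            (1.0, np.pi / 2, 12),
        ],
    )
    def test_known_values(self, ratio, expected, decimals):
        assert asr_transform(ratio) == pytest.approx(expected, abs=10.0**-decimals)

    @pytest.mark.parametrize("bad", [-0.01, 1.01, np.nan])
    def test_domain_error(self, bad):
        with pytest.raises(DomainError):
            asr_transform(bad)

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(derandomize=True, max_examples=200)
    def test_round_trip(self, f):
        assert asr_inverse(asr_transform(f)) == pytest.approx(f, abs=1e-12)

    def test_strictly_increasing(self):
        grid = np.linspace(0.0, 1.0, 1001)
        assert np.all(np.diff(asr_transform(grid)) > 0)


class TestRatioAndIntensity:
    def test_basic(self):
        ratio, intensity = compute_ratio_and_intensity(3000.0, 1000.0)
        assert ratio == pytest.approx(0.75)
        assert intensity == pytest.approx(3162.2777, abs=1e-3)
        assert intensity < 3200  # below the default filter threshold

    def test_boundary(self):
        ratio, intensity = compute_ratio_and_intensity(3200.0, 0.0)
        assert ratio == 1.0
        assert intensity == 3200.0  # at-threshold records are retained

    def test_zero_total_is_invalid(self):
        ratio, intensity = compute_ratio_and_intensity(0.0, 0.0)
        assert np.isnan(ratio)
        assert intensity == 0.0

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            compute_ratio_and_intensity(-1.0, 5.0)


class TestMeanModel:
    def test_symmetric_no_background(self):
        prm = MeanModelParams(1, 0.0, 0.0, 1.0)
        assert mean_model_eval(prm, 2) == pytest.approx(np.pi / 4, abs=1e-12)

    def test_unequal_sensitivity(self):
        prm = MeanModelParams(1, 0.0, 0.0, 2.0)
        # fraction 2 / (2 + 2*2) = 1/3
        assert mean_model_eval(prm, 2) == pytest.approx(
            np.arcsin(np.sqrt(1.0 / 3.0)), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_model_nesting(self, seed):
        rng = np.random.default_rng(seed)
        c1, c2 = rng.uniform(0.0, 0.5, 2)
        r = rng.uniform(0.2, 5.0)
        d = rng.uniform(0.0, 0.3)
        m1 = mean_model_eval(MeanModelParams(1, c1, c2, r), DOSAGES)
        m3d0 = mean_model_eval(MeanModelParams(3, c1, c2, r, 0.0), DOSAGES)
        np.testing.assert_array_equal(m1, m3d0)
        m2 = mean_model_eval(MeanModelParams(2, c1, c1, r), DOSAGES)
        m1cc = mean_model_eval(MeanModelParams(1, c1, c1, r), DOSAGES)
        np.testing.assert_array_equal(m2, m1cc)
        m4 = mean_model_eval(MeanModelParams(4, c2, c2, r, d), DOSAGES)
        m3cc = mean_model_eval(MeanModelParams(3, c2, c2, r, d), DOSAGES)
        np.testing.assert_array_equal(m4, m3cc)

    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.05, max_value=20.0),
        st.floats(min_value=0.0, max_value=0.5),
        st.sampled_from([1, 2, 3, 4]),
    )
    @settings(derandomize=True, max_examples=200)
    def test_means_monotone_and_distinct(self, c1, c2, r, d, model_id):
        if model_id in (2, 4):
            c2 = c1
        if model_id in (1, 2):
            d = 0.0
        mu = mean_model_eval(MeanModelParams(model_id, c1, c2, r, d), DOSAGES)
        assert np.all(np.diff(mu) > 0)
        assert len(np.unique(mu)) == 5

    def test_invalid_params_rejected(self):
        with pytest.raises(DomainError):
            MeanModelParams(1, -0.1, 0.0, 1.0)
        with pytest.raises(DomainError):
            MeanModelParams(2, 0.1, 0.2, 1.0)  # unequal backgrounds
        with pytest.raises(DomainError):
            MeanModelParams(1, 0.0, 0.0, 1.0, 0.1)  # curvature in a linear model
        with pytest.raises(DomainError):
            MeanModelParams(1, 0.0, 0.0, 0.0)  # r must be positive
        with pytest.raises(DomainError):
            MeanModelParams(7, 0.0, 0.0, 1.0)


class TestHweProportions:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (0.5, (0.0625, 0.25, 0.375, 0.25, 0.0625)),
            (1.0, (1.0, 0.0, 0.0, 0.0, 0.0)),
            (0.2, (0.0016, 0.0256, 0.1536, 0.4096, 0.4096)),
        ],
    )
    def test_known_values(self, p, expected):
        np.testing.assert_allclose(hwe_proportions(p), expected, atol=1e-12)

    def test_matches_binomial_pmf_oracle(self, rng):
        # pi over a-dosage x is Binomial(4, 1-p): nulliplex-a prob is p^4.
        for p in rng.uniform(0.0, 1.0, 1000):
            oracle = binom.pmf(np.arange(5), 4, 1.0 - p)
            assert np.max(np.abs(hwe_proportions(p) - oracle)) < 1e-12

    def test_sums_to_one(self, rng):
        for p in rng.uniform(0.0, 1.0, 50):
            assert hwe_proportions(p).sum() == pytest.approx(1.0, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            hwe_proportions(1.5)


class TestParameterCount:
    @pytest.mark.parametrize(
        "model_id, hwe, k",
        [
            (1, True, 5), (1, False, 8),
            (2, True, 4), (2, False, 7),
            (3, True, 6), (3, False, 9),
            (4, True, 5), (4, False, 8),
        ],
    )
    def test_counting_rule(self, model_id, hwe, k):
        assert parameter_count(model_id, hwe) == k

    def test_unknown_model(self):
        with pytest.raises(DomainError):
            parameter_count(5, True)
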