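import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogchange import (
    corrected_d,
    effect_size,
    interpret_d,
    mean_change_ci,
    pooled_sd,
    reliability,
    sensitivity_table,
)
from cogchange.sensitivity import sensitivity_from_summary


def changes_with_moments(mean, sd, n, rng=None):
    """A length-n vector with exactly the requested sample mean and SD (ddof=1)."""
    rng = rng or np.random.default_rng(0)
    z = rng.normal(size=n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


class TestMeanChangeCI:
    @pytest.mark.parametrize(
        "mean, sd, n, expected",
        [
            (1.66, 4.96, 62, (0.40, 2.92)),
            # published interval is (-0.07, 1.00); from the display-rounded
            # mean/SD the upper bound computes to 1.0089
            (0.47, 2.73, 101, (-0.07, 1.01)),
        ],
    )
    def test_t_interval_matches_published(self, mean, sd, n, expected):
        x = changes_with_moments(mean, sd, n)
        m, s, ci = mean_change_ci(x)
        assert (m, s) == (pytest.approx(mean), pytest.approx(sd))
        assert round(ci[0], 2) == expected[0]
        assert round(ci[1], 2) == expected[1]

    def test_constant_changes_give_degenerate_interval(self):
        m, s, ci = mean_change_ci([2.0, 2.0, 2.0, 2.0])
        assert s == 0 and ci == (2.0, 2.0)

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            mean_change_ci([1.0])


class TestPooledSD:
    def test_equal_sds_are_a_fixed_point(self):
        assert pooled_sd(3.5, 3.5) == pytest.approx(3.5)

    def test_arithmetic(self):
        assert pooled_sd(3, 4) == pytest.approx(math.sqrt(12.5))
        assert pooled_sd(0, 0) == 0

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            pooled_sd(-1, 2)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    sd1=st.floats(0, 50, allow_nan=False),
    sd2=st.floats(0, 50, allow_nan=False),
)
def test_pooled_sd_lies_between_inputs(sd1, sd2):
    pooled = pooled_sd(sd1, sd2)
    assert min(sd1, sd2) - 1e-9 <= pooled <= max(sd1, sd2) + 1e-9


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    mean=st.floats(-20, 20, allow_nan=False),
    pooled=st.floats(0.1, 50),
    r=st.floats(-0.99, 0.99),
    c=st.floats(0.01, 100),
)
def test_effect_chain_scale_invariant_and_nonnegative(mean, pooled, r, c):
    es = effect_size(mean, pooled)
    assert es >= 0
    assert effect_size(c * mean, c * pooled) == pytest.approx(es, rel=1e-9)
    assert corrected_d(es, r) >= 0


class TestEffectSize:
    @pytest.mark.parametrize(
        "mean_change, pooled, expected",
        [(1.66, 6.10, 0.27), (-2.13, 6.34, 0.34), (0.0, 5.0, 0.0)],
    )
    def test_absolute_value_convention(self, mean_change, pooled, expected):
        assert round(effect_size(mean_change, pooled), 2) == expected

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            effect_size(1.0, 0.0)

    def test_scale_invariance(self, rng):
        m, p = 1.7, 4.2
        for c in (0.5, 3.0, 100.0):
            assert effect_size(c * m, c * p) == pytest.approx(effect_size(m, p))


class TestReliability:
    def test_monotone_function_gives_perfect_reliability(self):
        y1 = [3, 1, 4, 1, 5, 9, 2, 6]
        y2 = [v**3 + 1 for v in y1]  # strictly increasing transform with ties kept
        assert reliability(sorted(set(y1)), sorted({v**3 for v in set(y1)})) == 1.0
        assert reliability([1, 2, 3, 5], [10, 20, 30, 50]) == 1.0

    def test_matches_brute_force_rank_pearson(self):
        y1, y2 = [1, 2, 3], [3, 1, 2]
        assert reliability(y1, y2) == pytest.approx(-0.5)
        # independent oracle: average-rank then Pearson
        r1 = np.argsort(np.argsort(y1)).astype(float)
        r2 = np.argsort(np.argsort(y2)).astype(float)
        assert reliability(y1, y2) == pytest.approx(np.corrcoef(r1, r2)[0, 1])

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            reliability([2, 2, 2], [1, 2, 3])

    def test_scale_invariance(self, rng):
        y1, y2 = rng.normal(size=50), rng.normal(size=50)
        assert reliability(3 * y1, 3 * y2) == pytest.approx(reliability(y1, y2))


class TestCorrectedD:
    #: published chains: (mean change, pooled SD, reliability) -> (ES, d)
    CHAINS = [
        ("aMCI", "AQ", 1.66, 6.10, 0.65, 0.27, 0.33),
        ("aMCI", "MMSE", -0.55, 2.47, 0.56, 0.22, 0.24),
        ("AD", "AQ", 2.49, 6.75, 0.64, 0.37, 0.43),
        ("AD", "MMSE", -2.13, 6.34, 0.79, 0.34, 0.52),
        ("CN", "AQ", 0.47, 3.37, 0.69, 0.14, 0.18),
        ("CN", "MMSE", 0.05, 2.47, 0.41, 0.02, 0.02),
    ]

    @pytest.mark.parametrize("group, inst, mc, pooled, r, es_exp, d_exp", CHAINS)
    def test_full_precision_chain_reproduces_published(
        self, group, inst, mc, pooled, r, es_exp, d_exp
    ):
        es, d, _ = sensitivity_from_summary(mc, pooled, r)
        assert round(es, 2) == es_exp
        assert round(d, 2) == d_exp

    def test_unrounded_convention_required(self):
        # carrying the display-rounded ES through the chain loses a digit
        assert round(corrected_d(0.27, 0.65), 2) == 0.32
        assert round(corrected_d(effect_size(1.66, 6.10), 0.65), 2) == 0.33

    def test_r_half_is_identity(self):
        assert corrected_d(0.42, 0.5) == pytest.approx(0.42)

    def test_monotone_in_reliability(self):
        ds = [corrected_d(0.3, r) for r in (0.0, 0.3, 0.6, 0.9)]
        assert ds == sorted(ds)

    def test_perfect_reliability_rejected(self):
        with pytest.raises(ValueError):
            corrected_d(0.3, 1.0)


class TestInterpretD:
    @pytest.mark.parametrize(
        "d, band",
        [
            (0.0, "trivial"),
            (0.18, "trivial"),
            (0.20, "small"),
            (0.43, "small"),
            (0.50, "moderate"),
            (0.52, "moderate"),
            (0.80, "large"),
            (0.84, "large"),
        ],
    )
    def test_bands_with_boundaries_assigned_upward(self, d, band):
        assert interpret_d(d) == band

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            interpret_d(-0.1)


class TestSensitivityTable:
    def test_single_group_cohort_restricts_table(self, ref_cohort):
        table = sensitivity_table(ref_cohort.subset("AD"))
        assert set(table["group"]) == {"AD"}
        assert set(table["instrument"]) == {"AQ", "FAQ", "MMSE"}

    def test_invariant_to_subject_order(self, ref_cohort):
        from cogchange import Cohort

        shuffled = Cohort(ref_cohort.df.sample(frac=1, random_state=5))
        a = sensitivity_table(ref_cohort).set_index(["group", "instrument"])
        b = sensitivity_table(shuffled).set_index(["group", "instrument"])
        for col in ("mean_change", "sd_change", "pooled_sd", "es", "reliability_r", "d"):
            assert np.allclose(a[col].astype(float), b[col].astype(float))

    def test_band_consistent_with_d(self, ref_cohort):
        table = sensitivity_table(ref_cohort)
        for _, row in table.iterrows():
            assert row["band"] == interpret_d(row["d"])
            assert row["ci95_low"] <= row["mean_change"] <= row["ci95_high"]
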