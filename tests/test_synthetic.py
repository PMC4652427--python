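import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cogchange import (
    generate_cohort,
    reference_config,
    reliability,
    truth_record,
)
from cogchange.instruments import INSTRUMENTS, STAGING_SCALES
from cogchange.simulate import _discretized_mean, _latent_mean


class TestReferenceConfig:
    def test_group_sizes_match_study(self):
        cfg = reference_config()
        assert {g: gc.n for g, gc in cfg.groups.items()} == {
            "CN": 101,
            "aMCI": 62,
            "AD": 39,
        }

    def test_rho_solved_from_change_variance_identity(self):
        # sd1 = sd2 = 6.10 and change SD 4.96 imply rho = 1 - 4.96^2/(2*6.10^2)
        cfg = reference_config()
        p = cfg.groups["aMCI"].instruments["AQ"]
        assert p.sd1 == p.sd2 == 6.10
        assert p.rho == pytest.approx(1 - 4.96**2 / (2 * 6.10**2))
        assert p.rho == pytest.approx(0.669, abs=5e-4)
        assert p.mu2 - p.mu1 == pytest.approx(1.66)

    def test_cn_mmse_mean_change(self):
        p = reference_config().groups["CN"].instruments["MMSE"]
        assert p.mu2 - p.mu1 == pytest.approx(0.05)

    def test_implausible_negative_rho_replaced_by_printed_reliability(self):
        # the published aMCI FAQ pooled SD is inconsistent with its change SD
        p = reference_config().groups["aMCI"].instruments["FAQ"]
        assert 0 < p.rho < 1
        assert p.rho == pytest.approx(0.63)
        sd_change = math.sqrt(2 * (1 - p.rho)) * p.sd1
        assert sd_change == pytest.approx(5.79, abs=1e-9)


class TestGenerator:
    def test_same_seed_gives_identical_cohorts(self):
        cfg = reference_config(seed=9)
        pd.testing.assert_frame_equal(generate_cohort(cfg).df, generate_cohort(cfg).df)

    def test_different_seed_gives_different_cohort(self):
        a = generate_cohort(reference_config(seed=1)).df
        b = generate_cohort(reference_config(seed=2)).df
        assert not a.equals(b)

    def test_empty_group_yields_no_records(self):
        cfg = reference_config(n_per_group={"CN": 10, "aMCI": 0, "AD": 5}, seed=0)
        cohort = generate_cohort(cfg)
        assert set(cohort.df["group"]) == {"CN", "AD"} and len(cohort) == 15

    def test_scores_respect_ranges_and_category_sets(self, ref_cohort):
        df = ref_cohort.df
        for name, inst in INSTRUMENTS.items():
            for v in (1, 2):
                col = df[f"{name}_y{v}"]
                assert col.between(inst.lo, inst.hi).all()
                assert (col == col.round()).all()
        for name, scale in STAGING_SCALES.items():
            for v in (1, 2):
                assert df[f"{name}_y{v}"].isin(scale.categories).all()

    def test_stage_never_improves_and_moves_at_most_one_category(self, ref_cohort):
        df = ref_cohort.df
        for name, scale in STAGING_SCALES.items():
            r1 = df[f"{name}_y1"].map(scale.rank)
            r2 = df[f"{name}_y2"].map(scale.rank)
            assert ((r2 - r1).isin([0, 1])).all()


class TestCalibration:
    def test_latent_mean_calibration_is_exact(self):
        """Latent means are solved so discretized observed means hit the target."""
        cfg = reference_config()
        for gc in cfg.groups.values():
            for p in gc.instruments.values():
                for target in (p.mu1, p.mu2):
                    mu = _latent_mean(target, p.sd1, p.lo, p.hi)
                    assert _discretized_mean(
                        mu, p.sd1, int(p.lo), int(p.hi)
                    ) == pytest.approx(target, abs=1e-8)

    def test_discretization_mean_bias_below_tenth_point(self, big_cohort):
        """Observed mean change stays within 0.1 points of the configured value."""
        cfg, cohort = big_cohort
        truth = truth_record(cfg).set_index(["group", "instrument"])
        for (group, inst), t in truth.iterrows():
            pairs = cohort.subset(group).paired_scores(inst)
            observed = (pairs["year2"] - pairs["year1"]).mean()
            mc_err = 3 * t.sd_change / math.sqrt(len(pairs))
            assert abs(observed - t.mean_change) < 0.1 + mc_err

    def test_latent_moments_converge_to_configured(self, big_latent_cohort):
        """Mean change and change SD within 3 SE; Spearman near latent rho."""
        cfg, cohort = big_latent_cohort
        truth = truth_record(cfg).set_index(["group", "instrument"])
        n = 10_000
        for (group, inst), t in truth.iterrows():
            pairs = cohort.subset(group).paired_scores(inst)
            change = pairs["year2"] - pairs["year1"]
            assert abs(change.mean() - t.mean_change) < 3 * t.sd_change / math.sqrt(n)
            assert abs(change.std(ddof=1) - t.sd_change) < 3 * t.sd_change / math.sqrt(2 * n)
            # Spearman of a bivariate normal sits slightly below Pearson rho:
            # population value is (6/pi) asin(rho/2)
            expected = 6 / math.pi * math.asin(t.rho / 2)
            r = reliability(pairs["year1"], pairs["year2"])
            assert abs(r - expected) < 3 / math.sqrt(n)
            assert abs(r - t.rho) < 0.04

    def test_effect_sizes_recovered_at_large_n(self, big_cohort):
        """Empirical ES at n=10,000 lands within 0.02 of the published AQ/MMSE values."""
        from cogchange import sensitivity_table
        from cogchange.reference import reference_row

        table = sensitivity_table(big_cohort[1]).set_index(["group", "instrument"])
        for group in ("CN", "aMCI", "AD"):
            for inst in ("AQ", "MMSE"):
                assert table.loc[(group, inst), "es"] == pytest.approx(
                    reference_row(group, inst).es, abs=0.02
                )


class TestTruthRecord:
    def test_passthrough_of_generating_parameters(self):
        cfg = reference_config(stage_betas={"AQ": math.log(1.20)})
        truth = truth_record(cfg).set_index(["group", "instrument"])
        assert truth.loc[("aMCI", "AQ"), "stage_beta"] == pytest.approx(math.log(1.20))
        assert truth.loc[("aMCI", "FAQ"), "stage_beta"] == 0.0
        assert truth.loc[("AD", "AQ"), "sd_change"] == pytest.approx(4.77)

    def test_invariant_to_seed(self):
        a = truth_record(reference_config(seed=1))
        b = truth_record(reference_config(seed=99))
        pd.testing.assert_frame_equal(a, b)

    def test_logistic_coupling_recovers_generating_or(self, rng):
        """Refitting stage increase on AQ change recovers OR = 1.20 on average."""
        from cogchange import compute_change_scores, dichotomize_increase, fit_univariate_logistic

        ors = []
        for rep in range(60):
            cfg = reference_config(seed=int(rng.integers(2**31)))
            cohort = generate_cohort(cfg)
            change = compute_change_scores(cohort)["AQ"]
            df = cohort.df.set_index("subject_id")
            y = [
                dichotomize_increase(a, b, "CDR")
                for a, b in zip(df["CDR_y1"], df["CDR_y2"])
            ]
            ors.append(fit_univariate_logistic(change, y).or_)
        assert np.mean(ors) == pytest.approx(1.20, abs=0.03)
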