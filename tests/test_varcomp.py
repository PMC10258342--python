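import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from seedtraits.simulate import SimConfig, TraitSpec, simulate_dataset
from seedtraits.trait_data import TraitDataset
from seedtraits.varcomp import (
    UnbalancedError,
    em_reml,
    fit_across_years,
    fit_single_year,
    lrt_genotype,
    lsd,
)

from conftest import make_dataset


class TestSingleYear:
    def test_hand_anova_oracle(self, toy_single_year):
        vc = fit_single_year(toy_single_year, "T", 2014)
        assert vc.ms_g == pytest.approx(8.0)
        assert vc.ms_e == pytest.approx(2.0)
        assert vc.sigma_g2 == pytest.approx(3.0)
        assert vc.sigma_e2 == pytest.approx(2.0)
        assert (vc.df_g, vc.df_e) == (2, 3)
        assert not vc.truncated
        # balanced-data invariant: MS_g = nr sigma_g2 + sigma_e2
        assert vc.ms_g == pytest.approx(2 * vc.sigma_g2 + vc.sigma_e2)

    def test_se_from_mean_square_variances(self, toy_single_year):
        vc = fit_single_year(toy_single_year, "T", 2014)
        assert vc.se_e == pytest.approx(np.sqrt(2 * 2.0**2 / 3))
        assert vc.se_g == pytest.approx(np.sqrt(2 * 8.0**2 / 2 + 2 * 2.0**2 / 3) / 2)

    def test_no_variation_gives_zero_components(self):
        ds = make_dataset(
            [(a, 2014, r, "T", 7.0) for a in "ABC" for r in (1, 2)]
        )
        vc = fit_single_year(ds, "T", 2014)
        assert vc.sigma_g2 == 0.0
        assert vc.sigma_e2 == 0.0

    def test_negative_estimate_clamped_and_flagged(self):
        # all accession means equal 2 -> MS_g = 0 < MS_e, clamp to 0
        ds = make_dataset(
            [("A", 2014, 1, "T", 1.0), ("A", 2014, 2, "T", 3.0),
             ("B", 2014, 1, "T", 3.0), ("B", 2014, 2, "T", 1.0),
             ("C", 2014, 1, "T", 2.0), ("C", 2014, 2, "T", 2.0)]
        )
        vc = fit_single_year(ds, "T", 2014)
        assert vc.sigma_g2 == 0.0
        assert vc.truncated

    def test_order_invariance(self, toy_single_year):
        rng = np.random.default_rng(1)
        shuffled = TraitDataset(
            toy_single_year.records.iloc[rng.permutation(6)].reset_index(drop=True)
        )
        a, b = fit_single_year(toy_single_year, "T", 2014), fit_single_year(shuffled, "T", 2014)
        assert a.sigma_g2 == b.sigma_g2 and a.sigma_e2 == b.sigma_e2

    def test_unbalanced_routed_to_em_reml(self, toy_single_year):
        ds = TraitDataset(toy_single_year.records.iloc[:-1].reset_index(drop=True))
        with pytest.raises(UnbalancedError, match="em_reml"):
            fit_single_year(ds, "T", 2014)

    def test_single_replicate_rejected(self):
        ds = make_dataset([("A", 2014, 1, "T", 1.0), ("B", 2014, 1, "T", 2.0)])
        with pytest.raises(ValueError, match="nr >= 2"):
            fit_single_year(ds, "T", 2014)

    @given(
        scale=st.floats(0.1, 50.0),
        shift=st.floats(-100.0, 100.0),
    )
    def test_scale_and_location_equivariance(self, scale, shift):
        rows = [(a, 2014, r, "T", v) for (a, r, v) in
                [("A", 1, 4.0), ("A", 2, 6.0), ("B", 1, 8.0), ("B", 2, 10.0),
                 ("C", 1, 6.0), ("C", 2, 8.0)]]
        base = fit_single_year(make_dataset(rows), "T", 2014)
        transformed = make_dataset(
            [(a, y, r, t, scale * v + shift) for (a, y, r, t, v) in rows]
        )
        vc = fit_single_year(transformed, "T", 2014)
        assert vc.sigma_g2 == pytest.approx(scale**2 * base.sigma_g2, rel=1e-9)
        assert vc.sigma_e2 == pytest.approx(scale**2 * base.sigma_e2, rel=1e-9)
        assert lsd(vc).lsd == pytest.approx(scale * lsd(base).lsd, rel=1e-9)


class TestAcrossYears:
    def test_additive_toy_exact(self, toy_across_years):
        vc = fit_across_years(toy_across_years, "T")
        assert vc.sigma_g2 == pytest.approx(1.0)
        assert vc.sigma_gy2 == pytest.approx(0.0, abs=1e-12)
        assert vc.sigma_e2 == pytest.approx(0.0, abs=1e-12)
        assert vc.year_means == {2014: pytest.approx(12.0), 2019: pytest.approx(8.0)}

    def test_all_equal_gives_zero(self):
        ds = make_dataset(
            [(a, y, r, "T", 5.0) for a in "AB" for y in (2014, 2019) for r in (1, 2)]
        )
        vc = fit_across_years(ds, "T")
        assert vc.sigma_g2 == vc.sigma_gy2 == vc.sigma_e2 == 0.0

    def test_monte_carlo_recovery_50_accessions(self):
        """Mean estimates over 400 simulations within 5% of the truth."""
        truth = dict(sigma_g2=0.2, sigma_gy2=0.05, sigma_e2=0.1)
        cfg = SimConfig(
            n_accessions=50, years=(2014, 2019), nr=3,
            traits=(TraitSpec("x", 10.0, 0.2, 0.05, 0.1),), seed=0,
        )
        seeds = np.random.SeedSequence(2024).generate_state(400) % 2**31
        est = {k: [] for k in truth}
        for s in seeds:
            vc = fit_across_years(
                simulate_dataset(dataclasses.replace(cfg, seed=int(s))), "x"
            )
            for k in truth:
                est[k].append(getattr(vc, k))
        for k, true_val in truth.items():
            assert np.mean(est[k]) == pytest.approx(true_val, rel=0.05)

    def test_single_year_data_rejected(self, toy_single_year):
        with pytest.raises(ValueError, match="fit_single_year"):
            fit_across_years(toy_single_year, "T")

    def test_missing_cell_routed_to_em_reml(self, toy_across_years):
        ds = TraitDataset(toy_across_years.records.iloc[:-1].reset_index(drop=True))
        with pytest.raises(UnbalancedError, match="em_reml"):
            fit_across_years(ds, "T")


class TestEmReml:
    def test_agrees_with_ems_on_toy(self, toy_single_year):
        ems = fit_single_year(toy_single_year, "T", 2014)
        em = em_reml(toy_single_year, "T", model="single_year", year=2014)
        assert em.sigma_g2 == pytest.approx(ems.sigma_g2, abs=1e-6)
        assert em.sigma_e2 == pytest.approx(ems.sigma_e2, abs=1e-6)

    def test_oracle_equivalence_sweep(self):
        """EM-REML matches the closed form on random interior datasets."""
        rng = np.random.default_rng(99)
        checked = 0
        while checked < 20:
            a = int(rng.integers(5, 15))
            nr = int(rng.integers(2, 5))
            cfg = SimConfig(
                n_accessions=a, years=(2014,), nr=nr,
                traits=(TraitSpec("x", 0.0, 1.0, 0.0, 0.5),),
                seed=int(rng.integers(2**31)),
            )
            ds = simulate_dataset(cfg)
            ems = fit_single_year(ds, "x", 2014)
            if ems.truncated or ems.sigma_g2 < 0.2:
                continue  # keep comfortably interior solutions
            em = em_reml(ds, "x", model="single_year", year=2014)
            assert abs(em.sigma_g2 - ems.sigma_g2) < 1e-6
            assert abs(em.sigma_e2 - ems.sigma_e2) < 1e-6
            checked += 1

    def test_across_years_agreement(self):
        cfg = SimConfig(
            n_accessions=10, years=(2014, 2019), nr=3,
            traits=(TraitSpec("x", 5.0, 1.0, 0.3, 0.5, (0.7, -0.7)),), seed=11,
        )
        ds = simulate_dataset(cfg)
        ems = fit_across_years(ds, "x")
        em = em_reml(ds, "x", model="across_years")
        assert em.sigma_g2 == pytest.approx(ems.sigma_g2, abs=1e-6)
        assert em.sigma_gy2 == pytest.approx(ems.sigma_gy2, abs=1e-6)
        assert em.sigma_e2 == pytest.approx(ems.sigma_e2, abs=1e-6)

    def test_matches_statsmodels_mixedlm(self):
        """Independent REML oracle: statsmodels MixedLM on the random-
        intercept model agrees with the balanced closed form."""
        import statsmodels.api as sm

        cfg = SimConfig(
            n_accessions=12, years=(2014,), nr=3,
            traits=(TraitSpec("x", 5.0, 0.8, 0.0, 0.4),), seed=6,
        )
        ds = simulate_dataset(cfg)
        ours = fit_single_year(ds, "x", 2014)
        df = ds.records
        fit = sm.MixedLM(
            df["value"], np.ones((len(df), 1)), groups=df["accession"]
        ).fit(reml=True)
        assert ours.sigma_g2 == pytest.approx(float(fit.cov_re.iloc[0, 0]), rel=1e-4)
        assert ours.sigma_e2 == pytest.approx(float(fit.scale), rel=1e-4)

    def test_handles_unbalanced_data(self):
        cfg = SimConfig(
            n_accessions=8, years=(2014,), nr=4,
            traits=(TraitSpec("x", 0.0, 1.0, 0.0, 0.5),), seed=3,
        )
        ds = simulate_dataset(cfg)
        # drop two records: closed form refuses, EM still estimates
        unb = TraitDataset(ds.records.iloc[:-2].reset_index(drop=True))
        with pytest.raises(UnbalancedError):
            fit_single_year(unb, "x", 2014)
        em = em_reml(unb, "x", model="single_year", year=2014)
        assert em.sigma_g2 >= 0 and em.sigma_e2 > 0

    def test_nonconvergence_reports_trajectory(self, toy_single_year):
        with pytest.raises(RuntimeError, match="iterations"):
            em_reml(toy_single_year, "T", model="single_year", year=2014, max_iter=2)


class TestLrt:
    def test_boundary_gives_zero_stat(self):
        ds = make_dataset(
            [("A", 2014, 1, "T", 1.0), ("A", 2014, 2, "T", 3.0),
             ("B", 2014, 1, "T", 3.0), ("B", 2014, 2, "T", 1.0)]
        )
        t = lrt_genotype(ds, "T", model="single_year", year=2014)
        assert t.lr_stat == 0.0
        assert t.p_value == 1.0

    def test_positive_stat_on_separated_means(self, toy_single_year):
        t = lrt_genotype(toy_single_year, "T", model="single_year", year=2014)
        assert t.lr_stat > 0
        assert 0 < t.p_value < 1
        # p is exactly the boundary-mixture transform of the statistic
        assert t.p_value == pytest.approx(0.5 * stats.chi2.sf(t.lr_stat, 1))

    def test_across_years_model(self, toy_across_years):
        t = lrt_genotype(toy_across_years, "T", model="across_years")
        assert t.lr_stat > 0

    def test_strong_signal_significant(self):
        cfg = SimConfig(
            n_accessions=15, years=(2014,), nr=3,
            traits=(TraitSpec("x", 0.0, 5.0, 0.0, 0.1),), seed=21,
        )
        t = lrt_genotype(simulate_dataset(cfg), "x", model="single_year", year=2014)
        assert t.p_value < 0.001


class TestLsd:
    def test_t_table_oracle(self, toy_single_year):
        # MS_e = 2, df_e = 3, n_eff = 2: lsd = t_{0.975,3} sqrt(2)
        vc = fit_single_year(toy_single_year, "T", 2014)
        res = lsd(vc, alpha=0.05, n_eff=2)
        assert res.lsd == pytest.approx(3.182 * np.sqrt(2), abs=2e-3)

    def test_zero_residual_gives_zero(self, toy_across_years):
        vc = fit_across_years(toy_across_years, "T")
        assert lsd(vc).lsd == 0.0

    def test_halving_alpha_increases_lsd(self, toy_single_year):
        vc = fit_single_year(toy_single_year, "T", 2014)
        assert lsd(vc, alpha=0.025).lsd > lsd(vc, alpha=0.05).lsd

    def test_default_n_eff_across_years(self):
        cfg = SimConfig(
            n_accessions=6, years=(2014, 2019), nr=3,
            traits=(TraitSpec("x", 0.0, 1.0, 0.1, 0.5),), seed=8,
        )
        vc = fit_across_years(simulate_dataset(cfg), "x")
        assert lsd(vc).n_eff == pytest.approx(6)  # nl * nr

    def test_invalid_alpha(self, toy_single_year):
        vc = fit_single_year(toy_single_year, "T", 2014)
        with pytest.raises(ValueError):
            lsd(vc, alpha=1.5)
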