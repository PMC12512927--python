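"""Moderated t, BH adjustment, Fisher combination and DMR chaining."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fibretype as ft
from fibretype.diffmeth import D0_INF, estimate_prior_variance, trigamma_inverse


def _paired_sheet(n_subjects, groups=("TI", "TII")):
    rows = []
    for i in range(n_subjects):
        for g in groups:
            rows.append({
                "sample_id": f"S{i:02d}_{g}", "subject_id": f"S{i:02d}",
                "group": g, "sex": "F" if i % 2 == 0 else "M",
            })
    return ft.validate_sample_sheet(pd.DataFrame(rows))


def _matrix(data, sheet):
    return pd.DataFrame(
        data, index=[f"f{i}" for i in range(len(data))], columns=sheet.index
    )


class TestModeratedT:
    def test_d0_zero_reproduces_classical_paired_t(self):
        rng = np.random.default_rng(0)
        sheet = _paired_sheet(8)
        data = rng.normal(size=(40, 16))
        m = _matrix(data, sheet)
        design = ft.DesignSpec(contrast=("TI", "TII"), paired=True)
        res = ft.ModeratedTModel(m, sheet, design).fit(prior_df=0.0)
        ti = m[[c for c in m if c.endswith("_TI")]].to_numpy()
        tii = m[[c for c in m if c.endswith("_TII")]].to_numpy()
        t_ref, p_ref = stats.ttest_rel(ti, tii, axis=1)
        np.testing.assert_allclose(res.table["t"], t_ref, atol=1e-10)
        np.testing.assert_allclose(res.table["p"], p_ref, atol=1e-10)

    def test_d0_infinite_shares_prior_variance(self):
        rng = np.random.default_rng(1)
        sheet = _paired_sheet(5)
        m = _matrix(rng.normal(size=(30, 10)), sheet)
        design = ft.DesignSpec(contrast=("TI", "TII"), paired=True)
        res = ft.ModeratedTModel(m, sheet, design).fit(
            prior_df=np.inf, prior_var=0.5
        )
        diffs = (
            m[[c for c in m if c.endswith("_TI")]].to_numpy()
            - m[[c for c in m if c.endswith("_TII")]].to_numpy()
        )
        effect = diffs.mean(axis=1)
        expect_t = effect / (np.sqrt(0.5) / np.sqrt(5))
        np.testing.assert_allclose(res.table["t"], expect_t, atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_hyperparameter_recovery_scaled_inv_chisq(self, seed):
        """Variances drawn from the d0=4, s0^2=0.5, df=10 hierarchy: the
        moment-matched estimates land within 25% of truth on average; any
        single draw stays within a factor-2 band."""
        rng = np.random.default_rng(100 + seed)
        d0_true, s0_true, df = 4.0, 0.5, 10.0
        true_var = d0_true * s0_true / rng.chisquare(d0_true, size=200)
        s2 = true_var * rng.chisquare(df, size=200) / df
        d0_hat, s0_hat = estimate_prior_variance(s2, df)
        assert 0.5 * d0_true < d0_hat < 2.0 * d0_true
        assert 0.5 * s0_true < s0_hat < 2.0 * s0_true

    def test_hyperparameter_recovery_mean_within_25pct(self):
        rng = np.random.default_rng(42)
        d0_true, s0_true, df = 4.0, 0.5, 10.0
        d0s, s0s = [], []
        for _ in range(10):
            true_var = d0_true * s0_true / rng.chisquare(d0_true, size=200)
            s2 = true_var * rng.chisquare(df, size=200) / df
            d0_hat, s0_hat = estimate_prior_variance(s2, df)
            d0s.append(d0_hat)
            s0s.append(s0_hat)
        assert abs(np.mean(d0s) - d0_true) / d0_true < 0.25
        assert abs(np.mean(s0s) - s0_true) / s0_true < 0.25

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma
        for y in (0.1, 1.0, 5.0, 50.0):
            x = float(polygamma(1, y))
            assert trigamma_inverse(x) == pytest.approx(y, rel=1e-6)

    def test_homoscedastic_variances_hit_the_infinite_prior_sentinel(self):
        s2 = np.full(500, 2.0)
        d0, s0 = estimate_prior_variance(s2, df=10.0)
        assert d0 == D0_INF

    def test_constant_rows_get_na_and_are_excluded_from_fdr(self):
        rng = np.random.default_rng(2)
        sheet = _paired_sheet(4)
        data = rng.normal(size=(10, 8))
        data[3] = 1.0  # constant across all samples
        m = _matrix(data, sheet)
        res = ft.ModeratedTModel(
            m, sheet, ft.DesignSpec(contrast=("TI", "TII"), paired=True)
        ).fit()
        assert np.isnan(res.table.iloc[3]["t"])
        assert np.isnan(res.table.iloc[3]["p_adj"])
        assert res.table["p_adj"].notna().sum() == 9


class TestPairResolve:
    def test_incomplete_blocks_dropped_with_warning(self):
        sheet = _paired_sheet(4)
        sheet = sheet.drop("S03_TII")  # S03 incomplete
        design = ft.DesignSpec(contrast=("TI", "TII"), paired=True)
        with pytest.warns(UserWarning, match="incomplete"):
            blocks, dropped = ft.pair_resolve(design, sheet)
        assert len(blocks) == 3
        assert dropped == ["S03"]

    def test_identical_pairs_give_zero_t(self):
        sheet = _paired_sheet(3)
        rng = np.random.default_rng(3)
        base = rng.normal(size=(5, 3))
        data = np.column_stack([base[:, [i // 2]] for i in range(6)])
        m = _matrix(data, sheet)
        res = ft.ModeratedTModel(
            m, sheet, ft.DesignSpec(contrast=("TI", "TII"), paired=True)
        ).fit()
        np.testing.assert_allclose(res.table["logFC"], 0.0, atol=1e-12)

    def test_no_complete_blocks_raises(self):
        # every subject holds only one contrast level
        sheet = _paired_sheet(2).drop(["S00_TII", "S01_TI"])
        design = ft.DesignSpec(contrast=("TI", "TII"), paired=True)
        with pytest.raises(ft.ValidationError):
            with pytest.warns(UserWarning):
                ft.pair_resolve(design, sheet)

    def test_paired_matches_unpaired_without_subject_effect(self):
        """With no subject random intercept the paired and unpaired effect
        estimates coincide; only df bookkeeping differs."""
        cfg = ft.SimConfig(n_cpgs=1000, n_dmp_true=100, n_subjects=8,
                           subject_sd_logit=0.0, sex_effect_cpgs=0, seed=9)
        beta, sheet, _ = ft.simulate_fibre_methylomes(cfg)
        m = ft.beta_to_m(beta)
        paired = ft.ModeratedTModel(
            m.values, sheet, ft.DesignSpec(contrast=("TI", "TII"), paired=True)
        ).fit()
        unpaired = ft.ModeratedTModel(
            m.values, sheet, ft.DesignSpec(contrast=("TI", "TII"), paired=False)
        ).fit()
        np.testing.assert_allclose(
            paired.table["logFC"], unpaired.table["logFC"], atol=1e-10
        )


class TestCovariatesAndInteraction:
    def test_sex_contrast_detects_sex_effect_cpgs(self):
        """Unpaired F-vs-M contrast within TI samples recovers the CpGs the
        generator shifted in females only."""
        cfg = ft.SimConfig(n_cpgs=3000, n_dmp_true=200, n_subjects=12,
                           sex_effect_cpgs=50, sex_effect_delta=0.15, seed=21)
        beta, sheet, truth = ft.simulate_fibre_methylomes(cfg)
        ti = sheet[sheet["group"] == "TI"]
        m = ft.beta_to_m(beta)
        design = ft.DesignSpec(grouping="sex", contrast=("F", "M"), paired=False)
        res = ft.ModeratedTModel(
            m.values[list(ti.index)], ti, design,
            effect_endog=beta.values[list(ti.index)],
        ).fit()
        sex_sites = truth.cpg_truth["sex_delta"] != 0
        called = res.table["p_adj"] < 0.05
        sens = (called & sex_sites).sum() / sex_sites.sum()
        assert sens > 0.8
        # sign: hypermethylated sites in F carry positive delta_beta
        up = truth.cpg_truth["sex_delta"] > 0
        assert (res.table.loc[up, "delta_beta"] > 0).mean() > 0.95

    def test_interaction_term_null_when_effects_are_additive(self):
        """Sex shifts applied equally to both fibre types leave the
        fibre-by-sex interaction null."""
        cfg = ft.SimConfig(n_cpgs=2000, n_dmp_true=200, n_subjects=12,
                           sex_effect_cpgs=50, sex_effect_delta=0.15, seed=22)
        beta, sheet, _ = ft.simulate_fibre_methylomes(cfg)
        fib = sheet[sheet["group"].isin(["TI", "TII"])]
        m = ft.beta_to_m(beta)
        design = ft.DesignSpec(
            grouping="group", contrast=("TI", "TII"),
            paired=False, interaction="sex",
        )
        res = ft.ModeratedTModel(m.values[list(fib.index)], fib, design).fit()
        assert (res.table["p_adj"].dropna() < 0.05).sum() == 0

    def test_covariate_adjustment_removes_confounded_shift(self):
        """A constant shift applied to one sex is absorbed by the covariate,
        so an unpaired sex-balanced group contrast stays null."""
        rng = np.random.default_rng(23)
        sheet = _paired_sheet(8)
        data = rng.normal(size=(50, 16))
        shift = (sheet["sex"] == "F").to_numpy(dtype=float) * 2.0
        m = _matrix(data + shift, sheet)
        design = ft.DesignSpec(contrast=("TI", "TII"), paired=False,
                               covariates=("sex",))
        res = ft.ModeratedTModel(m, sheet, design).fit()
        assert (res.table["p_adj"] < 0.05).sum() == 0


class TestBenjaminiHochberg:
    def test_hand_stepped_example(self):
        adj = ft.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        assert ft.benjamini_hochberg([0.37])[0] == pytest.approx(0.37)

    def test_agrees_with_brute_force_stepup(self):
        """Independent oracle: the literal step-up definition
        adj_i = min over j>=i of min(1, m*p_(j)/j)."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 50))
            m = len(p)
            order = np.argsort(p)
            brute = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                running = min(running, m * p[order[rank - 1]] / rank)
                brute[order[rank - 1]] = running
            np.testing.assert_allclose(ft.benjamini_hochberg(p), brute, atol=1e-12)

    def test_permutation_equivariance_and_na(self):
        p = np.array([0.3, np.nan, 0.01, 0.2])
        adj = ft.benjamini_hochberg(p)
        assert np.isnan(adj[1])
        perm = [3, 0, 2, 1]
        np.testing.assert_allclose(
            ft.benjamini_hochberg(p[perm])[:3], adj[perm][:3], atol=1e-15
        )

    def test_bounds(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=100)
        adj = ft.benjamini_hochberg(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()


class TestFisherCombine:
    def test_all_ones_and_identity(self):
        assert ft.fisher_combine([1.0, 1.0, 1.0]) == pytest.approx(1.0)
        assert ft.fisher_combine([0.2]) == pytest.approx(0.2, rel=1e-12)

    def test_agrees_with_scipy_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            p = rng.uniform(0.001, 1.0, size=rng.integers(1, 12))
            ref = stats.combine_pvalues(p, method="fisher").pvalue
            assert ft.fisher_combine(p) == pytest.approx(ref, rel=1e-12)

    def test_half_pvalues_known_chisq(self):
        """p = (0.5,)*4: X^2 = -2*4*ln(0.5) = 5.5452, chi2(8) upper tail."""
        x2 = -2 * 4 * np.log(0.5)
        assert x2 == pytest.approx(5.545177, abs=1e-5)
        expect = stats.chi2.sf(x2, 8)
        assert ft.fisher_combine([0.5] * 4) == pytest.approx(expect, rel=1e-12)

    def test_zero_p_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert ft.fisher_combine([0.0, 0.5]) == 0.0


def _dmp_frame(positions, deltas, p, chrom="chr1", p_adj=None):
    idx = pd.Index([f"cg{i:08d}" for i in range(len(positions))], name="probe_id")
    dmps = pd.DataFrame(
        {
            "logFC": np.sign(deltas), "delta_beta": deltas,
            "t": np.sign(deltas), "p": p,
            "p_adj": p if p_adj is None else p_adj,
        },
        index=idx,
    )
    ann = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "gene": "GENEA"}, index=idx
    )
    return dmps, ann


class TestCallDmrs:
    def test_single_chain(self):
        dmps, ann = _dmp_frame([100, 200, 300, 400, 500], [0.2] * 5, [1e-4] * 5)
        out = ft.call_dmrs(dmps, ann)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["n_cpgs"], row["start"], row["end"]) == (5, 100, 500)
        assert row["direction"] == "hyper"

    def test_large_gap_splits_into_two_regions(self):
        dmps, ann = _dmp_frame([100, 200, 300, 5300, 5400], [0.2] * 5, [1e-4] * 5)
        out = ft.call_dmrs(dmps, ann)
        assert sorted(out["n_cpgs"]) == [2, 3]
        small = out[out["n_cpgs"] == 3].iloc[0]
        assert not small["robust"]  # < 4 CpGs can never be robust

    def test_alternating_signs_yield_no_region(self):
        dmps, ann = _dmp_frame(
            [100, 200, 300, 400], [0.2, -0.2, 0.2, -0.2], [1e-4] * 4
        )
        assert len(ft.call_dmrs(dmps, ann)) == 0

    def test_robust_rule_exactly_enforced(self):
        dmps, ann = _dmp_frame([100, 200, 300, 400], [0.2] * 4, [0.04] * 4)
        out = ft.call_dmrs(dmps, ann)
        fp = ft.fisher_combine([0.04] * 4)
        assert out.iloc[0]["fisher_p"] == pytest.approx(fp)
        assert bool(out.iloc[0]["robust"]) == (fp < 0.001 and 4 >= 4)

    def test_members_disjoint_and_position_ties_collapsed(self):
        dmps, ann = _dmp_frame(
            [100, 100, 200, 300, 400], [0.2] * 5, [1e-4] * 5
        )
        out = ft.call_dmrs(dmps, ann)
        probes = ",".join(out["probes"]).split(",")
        assert len(probes) == len(set(probes))
        assert out["n_cpgs"].sum() == 4  # duplicate position collapsed

    def test_insignificant_cpgs_ignored(self):
        dmps, ann = _dmp_frame([100, 200, 300], [0.2] * 3, [0.9] * 3)
        assert len(ft.call_dmrs(dmps, ann)) == 0


class TestRobustDmps:
    def test_hand_filter_on_fixture(self):
        dmps = pd.DataFrame(
            {
                "logFC": [1, 1, 1, -1, -1, 1],
                "delta_beta": [0.15, 0.05, 0.2, -0.12, -0.3, 0.4],
                "t": [5, 1, 6, -4, -7, 2],
                "p": [1e-6] * 6,
                "p_adj": [1e-5, 1e-5, 0.1, 1e-4, 1e-6, 0.5],
            },
            index=[f"cg{i}" for i in range(6)],
        )
        out = ft.call_robust_dmps(dmps, fdr_max=0.001, min_delta=0.10)
        assert set(out.index) == {"cg0", "cg3", "cg4"}

    def test_empty_and_vacuous_thresholds(self):
        empty = ft.call_robust_dmps(pd.DataFrame(columns=["logFC", "delta_beta", "p_adj"]))
        assert empty.empty
        dmps = pd.DataFrame(
            {"logFC": [1.0], "delta_beta": [0.01], "p": [0.9], "p_adj": [0.99]},
            index=["cg0"],
        )
        assert len(ft.call_robust_dmps(dmps, fdr_max=1.01, min_delta=0.0)) == 1
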