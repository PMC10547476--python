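import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isletwave import integrate as ig
from isletwave import synthgen as sg


class TestZscore:
    def test_three_point_example(self):
        np.testing.assert_allclose(ig.zscore(np.array([1.0, 2.0, 3.0])), [-1, 0, 1])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=40, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_output_has_zero_mean_unit_sd(self, xs):
        from hypothesis import assume

        assume(np.std(xs) > 1e-6)  # numerically degenerate spreads aside
        z = ig.zscore(np.array(xs))
        assert abs(z.mean()) < 1e-9
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_constant_column_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            z = ig.zscore(np.array([5.0, 5.0, 5.0]))
        assert np.isnan(z).all()

    def test_missing_values_stay_missing(self):
        z = ig.zscore(pd.Series([1.0, np.nan, 3.0, 5.0]))
        assert np.isnan(z[1])
        assert z.dropna().mean() == pytest.approx(0.0, abs=1e-12)


class TestNormalScores:
    def test_normal_quantile_input_is_fixed_point(self):
        from scipy import stats

        n = 25
        q = 5.0 + 2.0 * stats.norm.ppf(np.arange(1, n + 1) / (n + 1))
        np.testing.assert_allclose(ig.normal_scores(q), q, atol=1e-9)

    def test_preserves_mean_and_variance(self):
        x = np.random.default_rng(4).exponential(size=30)
        ns = ig.normal_scores(x)
        assert ns.mean() == pytest.approx(x.mean(), abs=1e-12)
        assert ns.std(ddof=1) == pytest.approx(x.std(ddof=1), abs=1e-12)

    def test_monotone_transform_invariance_of_ranks(self):
        x = np.random.default_rng(5).normal(size=20)
        a = ig.normal_scores(x)
        b = ig.normal_scores(np.exp(x))
        assert (np.argsort(a) == np.argsort(b)).all()

    def test_ties_share_average_rank_quantile(self):
        out = ig.normal_scores(np.array([1.0, 2.0, 2.0, 3.0]))
        assert out[1] == pytest.approx(out[2])


class TestPearson:
    def test_self_correlation_is_one(self):
        x = np.array([1.0, 4.0, 2.0, 8.0])
        assert ig.pearson(x, x)[0] == pytest.approx(1.0)

    def test_negation_flips_sign(self):
        x = np.array([1.0, 4.0, 2.0, 8.0])
        assert ig.pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r, n = ig.pearson([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)
        assert n == 4

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=12), rng.normal(size=12)
        r0, _ = ig.pearson(x, y)
        r1, _ = ig.pearson(3.0 * x + 7.0, 0.5 * y - 2.0)
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_insufficient_pairs_gives_missing(self):
        r, n = ig.pearson([1.0, np.nan, 3.0], [np.nan, 2.0, 4.0])
        assert np.isnan(r) and n == 1


class TestCorrelateMatrix:
    def _fixture(self, seed=1):
        params = sg.make_planted_cohort_params(n_animals=16, seed=seed)
        params["strain"] = ["S%d" % (i % 4) for i in range(16)]
        params["sex"] = ["M", "F"] * 8
        spec = sg.PlantSpec(
            n_proteins=20, planted=(("P1", "8G_active_min", 1.0),), noise_sd=0.0, seed=seed
        )
        prot = sg.make_protein_matrix(params.drop(columns=["strain", "sex"]), spec)
        prot["strain"] = params["strain"]
        prot["sex"] = params["sex"]
        return params, prot

    def test_planted_perfect_correlation_recovered(self):
        params, prot = self._fixture()
        res = ig.correlate_matrix(params, prot)
        r = res.query("parameter == '8G_active_min' and protein == 'P1'").r.iloc[0]
        assert r == pytest.approx(1.0)

    def test_consistent_row_permutation_leaves_r_unchanged(self):
        params, prot = self._fixture()
        res0 = ig.correlate_matrix(params, prot)
        perm = np.random.default_rng(0).permutation(16)
        res1 = ig.correlate_matrix(params.iloc[perm], prot)
        pd.testing.assert_frame_equal(
            res0.sort_values(["parameter", "protein"]).reset_index(drop=True),
            res1.sort_values(["parameter", "protein"]).reset_index(drop=True),
        )

    def test_null_distribution_moments(self):
        """100 null proteins at n=16: mean r ~ 0 and SD within 10% of
        1/sqrt(n-1)."""
        params = sg.make_planted_cohort_params(n_animals=16, seed=2)
        prot = sg.make_protein_matrix(params, sg.PlantSpec(n_proteins=100, seed=2))
        res = ig.correlate_matrix(params, prot)
        rs = res.r.to_numpy()
        assert abs(rs.mean()) < 0.03
        assert rs.std() == pytest.approx(1 / np.sqrt(15), rel=0.12)

    def test_zscore_invariance(self):
        params, prot = self._fixture()
        res_raw = ig.correlate_matrix(params, prot)
        zs = ig.zscore_frame(params)
        res_z = ig.correlate_matrix(zs, prot)
        np.testing.assert_allclose(res_raw.r, res_z.r, atol=1e-12)

    def test_group_alignment_uses_strain_sex_means(self):
        params, prot = self._fixture()
        res = ig.correlate_matrix(params, prot, align="group")
        assert res.n_used.max() <= 8  # 4 strains x 2 sexes
        r = res.query("parameter == '8G_active_min' and protein == 'P1'").r.iloc[0]
        assert r == pytest.approx(1.0)  # group means of identical columns

    def test_scope_restriction_recomputes_on_subset(self):
        params, prot = self._fixture()
        res = ig.correlate_matrix(params, prot, scope=["S0", "S1"])
        assert res.n_used.max() == 8

    def test_no_shared_keys_is_alignment_error(self):
        params, prot = self._fixture()
        prot = prot.set_axis([f"other_{i}" for i in range(16)])
        with pytest.raises(ValueError, match="shared"):
            ig.correlate_matrix(params, prot)

    def test_too_few_points_returns_missing_not_number(self):
        params, prot = self._fixture()
        res = ig.correlate_matrix(params.iloc[:2], prot.iloc[:2])
        assert res.r.isna().all()


class TestFlagCandidates:
    def _corr(self, rs_by_param):
        rows = []
        for prot, rdict in rs_by_param.items():
            for par in ig.DEFAULT_FOCUS:
                rows.append((par, prot, rdict.get(par, 0.0), 16))
        return pd.DataFrame(rows, columns=["parameter", "protein", "r", "n_used"])

    def test_three_high_focus_parameters_flag(self):
        res = self._corr(
            {"P": {"2G_avg": 0.5, "8G_active_min": -0.6, "8G_pulse_min": 0.7}}
        )
        out = ig.flag_candidates(res)
        assert out.n_high.iloc[0] == 3 and bool(out.flagged.iloc[0])

    def test_boundary_049_not_flagged(self):
        res = self._corr({"P": {"2G_avg": 0.49, "8G_active_min": 0.49, "8G_pulse_min": 0.49}})
        assert not ig.flag_candidates(res).flagged.iloc[0]

    def test_boundary_exactly_half_counts(self):
        res = self._corr({"P": {p: 0.5 for p in ig.DEFAULT_FOCUS[:3]}})
        assert ig.flag_candidates(res).flagged.iloc[0]

    def test_unknown_focus_id_is_config_error(self):
        res = self._corr({"P": {}})
        with pytest.raises(ValueError, match="focus"):
            ig.flag_candidates(res, focus=("nonexistent",))

    def test_monotone_in_threshold(self):
        res = self._corr(
            {
                "A": {p: 0.55 for p in ig.DEFAULT_FOCUS[:3]},
                "B": {p: 0.45 for p in ig.DEFAULT_FOCUS[:4]},
            }
        )
        high = ig.flag_candidates(res, threshold=0.5)
        low = ig.flag_candidates(res, threshold=0.4)
        flagged_high = set(high[high.flagged].protein)
        flagged_low = set(low[low.flagged].protein)
        assert flagged_high <= flagged_low

    def test_planted_regulator_recovery(self):
        """5 regulators at per-parameter |r| = 0.9 on the three 8G duration
        parameters, 95 nulls, n = 16, seed 1: all 5 flagged, at most 2
        false positives."""
        params = sg.make_planted_cohort_params(n_animals=16, seed=1)
        planted = []
        for i in range(5):
            sign = 1.0 if i % 2 == 0 else -1.0
            for par in ("8G_active_min", "8G_pulse_min", "8G_silent_min"):
                planted.append((f"reg_{i + 1}", par, sign * 0.9))
        prot = sg.make_protein_matrix(
            params, sg.PlantSpec(n_proteins=100, planted=tuple(planted), noise_sd=1.0, seed=1)
        )
        res = ig.correlate_matrix(params, prot)
        flags = ig.flag_candidates(res)
        flagged = set(flags[flags.flagged].protein)
        assert {f"reg_{i}" for i in range(1, 6)} <= flagged
        assert len(flagged - {f"reg_{i}" for i in range(1, 6)}) <= 2


class TestTermEffects:
    def _design(self, n_per=8):
        strains = np.repeat(["A", "B", "C", "D"], n_per)
        sex = np.tile(["M", "F"], 2 * n_per)
        return strains, sex

    def test_pure_strain_means_give_tiny_strain_p_and_zero_sex_effect(self):
        strains, sex = self._design()
        y = np.select([strains == s for s in "ABCD"], [0.0, 1.0, 2.0, 3.0])
        te = ig.term_effects(y, strains, sex).set_index("term")
        assert te.loc["strain", "p_value"] < 1e-10
        assert te.loc["sex", "effect_sd_ratio"] == pytest.approx(0.0, abs=1e-9)

    def test_null_trait_strain_p_roughly_uniform(self):
        """200 i.i.d. traits: fraction of strain p-values < 0.1 within
        binomial bounds (4-16%)."""
        strains, sex = self._design()
        rng = np.random.default_rng(1)
        ps = [
            ig.term_effects(rng.normal(size=len(strains)), strains, sex)
            .set_index("term")
            .loc["strain", "p_value"]
            for _ in range(200)
        ]
        frac = np.mean(np.array(ps) < 0.1)
        assert 0.04 <= frac <= 0.16

    def test_label_permutation_destroys_planted_strain_effect(self):
        strains, sex = self._design()
        rng = np.random.default_rng(2)
        y = np.select([strains == s for s in "ABCD"], [0.0, 2.0, 4.0, 6.0]) + rng.normal(
            0, 0.5, len(strains)
        )
        p_true = ig.term_effects(y, strains, sex).set_index("term").loc["strain", "p_value"]
        perms = []
        for _ in range(20):
            perm = rng.permutation(len(strains))
            perms.append(
                ig.term_effects(y, strains[perm], sex)
                .set_index("term")
                .loc["strain", "p_value"]
            )
        assert p_true < 1e-6
        assert np.median(perms) > 0.1

    def test_signal_row_present_with_valid_p(self):
        strains, sex = self._design()
        y = np.random.default_rng(3).normal(size=len(strains))
        te = ig.term_effects(y, strains, sex).set_index("term")
        assert 0.0 < te.loc["signal", "p_value"] <= 1.0
        assert te.loc["signal", "effect_sd_ratio"] >= 0.0
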