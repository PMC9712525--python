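"""Replication battery and inverse-variance meta-analysis."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import transewas as tw

from conftest import make_result


class TestTopK:
    def test_k1_is_argmin(self):
        t = make_result(["a", "b", "c"], [0.1, 0.2, 0.3], [0.5, 0.01, 0.9])
        assert tw.top_k_select(t, 1) == ["b"]

    def test_restriction_promotes_second_best(self):
        t = make_result(list("abcdef"), [0.1, -0.2, 0.3, 0.1, -0.1, 0.2],
                        [0.01, 0.02, 0.03, 0.5, 0.6, 0.7])
        # hand-sorted: a, b, c, d, e, f; removing 'a' promotes 'b'
        assert tw.top_k_select(t, 2, restrict_to={"b", "c", "d", "e", "f"}) \
            == ["b", "c"]

    def test_ties_break_by_abs_effect_then_id(self):
        t = make_result(["a", "b", "c"], [0.1, 0.5, 0.5], [0.2, 0.2, 0.2])
        assert tw.top_k_select(t, 3) == ["b", "c", "a"]

    def test_saturation_returns_all_with_warning(self):
        t = make_result(["a", "b"], [0.1, 0.2], [0.5, 0.6])
        with pytest.warns(UserWarning):
            assert tw.top_k_select(t, 10) == ["a", "b"]

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(0)
        t = make_result([f"p{i}" for i in range(30)], rng.normal(size=30),
                        rng.uniform(size=30))
        shuffled = t.sample(frac=1, random_state=1).reset_index(drop=True)
        assert tw.top_k_select(t, 10) == tw.top_k_select(shuffled, 10)


class TestLookup:
    def test_top25_site_replicates_at_0002_but_not_family(self):
        """A replication p of 0.001 clears 0.05/25 = 0.002 but not the
        six-family threshold 0.05/150 = 0.0003."""
        ids = [f"p{i}" for i in range(30)]
        disc = make_result(ids, np.linspace(0.05, 0.01, 30),
                           np.linspace(1e-6, 0.5, 30))
        rep_p = np.full(30, 0.9)
        rep_p[0] = 0.001
        rep = make_result(ids, np.linspace(0.05, 0.01, 30), rep_p)
        look = tw.lookup_replication(disc, rep, k=25)
        row = look.set_index("probe_id").loc["p0"]
        assert bool(row["replicated"]) is True
        assert bool(row["survives_family"]) is False
        assert look.attrs["threshold"] == pytest.approx(0.002)
        assert look.attrs["family_threshold"] == pytest.approx(0.05 / 150)

    def test_null_replication_no_flags(self):
        ids = [f"p{i}" for i in range(30)]
        disc = make_result(ids, np.ones(30), np.linspace(1e-5, 0.9, 30))
        rep = make_result(ids, np.ones(30), np.ones(30))
        look = tw.lookup_replication(disc, rep, k=25)
        assert not look["replicated"].any()

    def test_flags_match_brute_force(self):
        rng = np.random.default_rng(3)
        ids = [f"p{i}" for i in range(60)]
        disc = make_result(ids, rng.normal(size=60), rng.uniform(size=60))
        rep = make_result(ids, rng.normal(size=60), rng.uniform(size=60))
        look = tw.lookup_replication(disc, rep, k=25)
        rep_idx = rep.set_index("probe_id")
        for _, row in look.iterrows():
            assert row["replicated"] == (
                rep_idx.at[row["probe_id"], "pvalue"] < 0.05 / 25)

    def test_disjoint_probe_universes_rejected(self):
        disc = make_result(["a"], [0.1], [0.01])
        rep = make_result(["b"], [0.1], [0.01])
        with pytest.raises(ValueError):
            tw.lookup_replication(disc, rep)


class TestEffectCorrelation:
    def test_identity_and_antisymmetry(self):
        rng = np.random.default_rng(1)
        ids = [f"p{i}" for i in range(40)]
        eff = rng.normal(size=40)
        disc = make_result(ids, eff, rng.uniform(size=40))
        same = tw.effectsize_correlation(disc, disc, ks=(10, 25))
        assert np.allclose(same["pearson_r"], 1.0)
        neg = make_result(ids, -eff, disc["pvalue"])
        anti = tw.effectsize_correlation(disc, neg, ks=(10, 25))
        assert np.allclose(anti["pearson_r"], -1.0)

    def test_matches_closed_form_pearson(self):
        rng = np.random.default_rng(2)
        ids = [f"p{i}" for i in range(10)]
        a, b = rng.normal(size=10), rng.normal(size=10)
        disc = make_result(ids, a, np.linspace(0.001, 0.01, 10))
        rep = make_result(ids, b, np.linspace(0.001, 0.01, 10))
        out = tw.effectsize_correlation(disc, rep, ks=(10,))
        top = tw.top_k_select(disc, 10)
        aa = disc.set_index("probe_id").loc[top, "effect"]
        bb = rep.set_index("probe_id").loc[top, "effect"]
        r_manual = (((aa - aa.mean()) * (bb - bb.mean())).sum()
                    / math.sqrt(((aa - aa.mean()) ** 2).sum()
                                * ((bb - bb.mean()) ** 2).sum()))
        assert out["pearson_r"].iloc[0] == pytest.approx(r_manual, abs=1e-12)

    def test_constant_vector_reported_missing(self):
        ids = [f"p{i}" for i in range(5)]
        disc = make_result(ids, np.ones(5), np.linspace(0.01, 0.05, 5))
        rep = make_result(ids, np.arange(5.0), np.linspace(0.01, 0.05, 5))
        with pytest.warns(UserWarning, match="constant"):
            out = tw.effectsize_correlation(disc, rep, ks=(5,))
        assert np.isnan(out["pearson_r"].iloc[0])


class TestSignBinomial:
    def test_zero_successes_gives_p_one(self):
        ids = [f"p{i}" for i in range(25)]
        disc = make_result(ids, np.ones(25), np.linspace(1e-4, 0.01, 25))
        rep = make_result(ids, np.ones(25), np.ones(25))
        out = tw.sign_binomial_test(disc, rep, ks=(25,))
        assert out["binomial_p"].iloc[0] == pytest.approx(1.0)

    def test_matches_direct_binomial_sum(self):
        """3 successes in 25 at p0 = 0.025 equals the explicit tail sum."""
        ids = [f"p{i}" for i in range(25)]
        disc = make_result(ids, np.ones(25), np.linspace(1e-4, 0.01, 25))
        rep_p = np.ones(25)
        rep_p[:3] = 0.01
        rep = make_result(ids, np.ones(25), rep_p)
        out = tw.sign_binomial_test(disc, rep, ks=(25,))
        p0 = 0.025
        oracle = sum(
            math.comb(25, i) * p0 ** i * (1 - p0) ** (25 - i)
            for i in range(3, 26)
        )
        assert out["binomial_p"].iloc[0] == pytest.approx(oracle, rel=1e-12)

    def test_all_successes_closed_form(self):
        ids = [f"p{i}" for i in range(10)]
        disc = make_result(ids, np.ones(10), np.linspace(1e-4, 0.01, 10))
        rep = make_result(ids, np.ones(10), np.full(10, 0.001))
        out = tw.sign_binomial_test(disc, rep, ks=(10,))
        assert out["binomial_p"].iloc[0] == pytest.approx(0.025 ** 10, rel=1e-9)

    def test_zero_discovery_effect_excluded(self):
        ids = ["a", "b", "c"]
        disc = make_result(ids, [0.0, 1.0, 1.0], [0.001, 0.002, 0.003])
        rep = make_result(ids, [1.0, 1.0, 1.0], [0.01, 0.01, 0.01])
        with pytest.warns(UserWarning, match="zero discovery effect"):
            out = tw.sign_binomial_test(disc, rep, ks=(3,))
        assert out["n_trials"].iloc[0] == 2

    def test_alternative_p0_convention(self):
        ids = [f"p{i}" for i in range(10)]
        disc = make_result(ids, np.ones(10), np.linspace(1e-4, 0.01, 10))
        rep = make_result(ids, np.ones(10), np.full(10, 0.001))
        out = tw.sign_binomial_test(disc, rep, ks=(10,), p0=0.05)
        assert out["binomial_p"].iloc[0] == pytest.approx(0.05 ** 10, rel=1e-9)


class TestCrossGroup:
    def test_self_agreement_perfect(self):
        rng = np.random.default_rng(4)
        ids = [f"p{i}" for i in range(50)]
        res = make_result(ids, rng.normal(size=50), rng.uniform(size=50))
        rep = tw.cross_group_agreement(res, res, ks=(10, 25))
        assert np.allclose(rep.correlations["pearson_r"], 1.0)

    def test_timepoint_lookup_uses_alpha_over_three(self):
        """p = 0.02 fails the 0.05/3 ~ 0.0167 timepoint convention."""
        ids = [f"p{i}" for i in range(30)]
        disc = make_result(ids, np.ones(30), np.linspace(1e-5, 0.5, 30))
        rep_p = np.full(30, 0.02)
        rep = make_result(ids, np.ones(30), rep_p)
        agree = tw.cross_group_agreement(disc, rep, ks=(10,),
                                         timepoint_lookup=True)
        assert not agree.lookup["replicated"].any()
        assert agree.lookup.attrs["threshold"] == pytest.approx(0.05 / 3)
        # the same replication p clears the default 0.05/25-free convention
        plain = tw.cross_group_agreement(disc, rep, ks=(10,))
        assert plain.lookup.attrs["threshold"] == pytest.approx(0.05 / 25)

    def test_report_roundtrips_to_json(self, tmp_path):
        rng = np.random.default_rng(5)
        ids = [f"p{i}" for i in range(30)]
        res = make_result(ids, rng.normal(size=30), rng.uniform(size=30))
        rep = tw.replication_report(res, res, ks=(10,), k_lookup=10)
        rep.to_json(tmp_path / "r.json")
        import json
        loaded = json.loads((tmp_path / "r.json").read_text())
        assert loaded["params"]["k_lookup"] == 10
        assert len(loaded["lookup"]) == 10


class TestMeta:
    def test_identical_studies_closed_form(self):
        a = make_result(["p"], [0.5], [0.5], ses=[0.1])
        meta = tw.fixed_effects_meta([a, a])
        row = meta.iloc[0]
        assert row["effect_meta"] == pytest.approx(0.5)
        assert row["se_meta"] == pytest.approx(0.1 / math.sqrt(2), rel=1e-12)

    def test_two_study_weight_arithmetic(self):
        """(1.0, se 0.5) + (0.0, se 1.0): weights 4 and 1 give effect 0.8
        and pooled SE 5^{-1/2}."""
        a = make_result(["p"], [1.0], [0.5], ses=[0.5])
        b = make_result(["p"], [0.0], [0.5], ses=[1.0])
        meta = tw.fixed_effects_meta([a, b])
        row = meta.iloc[0]
        assert row["effect_meta"] == pytest.approx(0.8, abs=1e-12)
        assert row["se_meta"] == pytest.approx(5 ** -0.5, rel=1e-12)
        z = 0.8 / 5 ** -0.5
        assert row["pvalue"] == pytest.approx(2 * stats.norm.sf(z), rel=1e-12)

    def test_se_shrinks_as_sqrt_k(self):
        a = make_result(["p"], [0.3], [0.5], ses=[0.2])
        for k in (2, 3, 5, 8):
            meta = tw.fixed_effects_meta([a] * k)
            assert meta["se_meta"].iloc[0] == pytest.approx(
                0.2 / math.sqrt(k), rel=1e-12)

    def test_partial_overlap_flagged(self):
        a = make_result(["p", "q"], [0.5, 0.2], [0.5, 0.5], ses=[0.1, 0.1])
        b = make_result(["p"], [0.5], [0.5], ses=[0.1])
        meta = tw.fixed_effects_meta([a, b]).set_index("probe_id")
        assert meta.at["p", "n_studies"] == 2
        assert meta.at["q", "n_studies"] == 1
        common = tw.fixed_effects_meta([a, b], common_only=True)
        assert list(common["probe_id"]) == ["p"]

    def test_se_never_exceeds_min_input(self):
        rng = np.random.default_rng(6)
        ids = [f"p{i}" for i in range(20)]
        a = make_result(ids, rng.normal(size=20), rng.uniform(size=20),
                        ses=rng.uniform(0.05, 0.5, 20))
        b = make_result(ids, rng.normal(size=20), rng.uniform(size=20),
                        ses=rng.uniform(0.05, 0.5, 20))
        meta = tw.fixed_effects_meta([a, b]).set_index("probe_id")
        for pid in ids:
            lo = min(a.set_index("probe_id").at[pid, "se"],
                     b.set_index("probe_id").at[pid, "se"])
            assert meta.at[pid, "se_meta"] <= lo + 1e-15

    def test_row_order_invariance(self):
        rng = np.random.default_rng(7)
        ids = [f"p{i}" for i in range(15)]
        a = make_result(ids, rng.normal(size=15), rng.uniform(size=15))
        b = make_result(ids, rng.normal(size=15), rng.uniform(size=15))
        m1 = tw.fixed_effects_meta([a, b])
        m2 = tw.fixed_effects_meta(
            [a.sample(frac=1, random_state=0), b.sample(frac=1, random_state=1)])
        pd.testing.assert_frame_equal(m1, m2)

    def test_single_result_rejected(self):
        with pytest.raises(ValueError):
            tw.fixed_effects_meta([make_result(["p"], [0.1], [0.5])])
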