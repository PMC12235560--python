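"""Random-intercept LMMs, BH FDR screening, and rater agreement."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from _oracles import brute_force_bh

from motionbag import InputError, bh_fdr, fit_lmm, pc_motion_tests, rater_agreement
from motionbag.exceptions import FitError


def make_session_data(n_sub, contrasts=(0.0, 1.0, 2.5), sd_u=1.0, sd_e=1.0, seed=0,
                      outcome="y"):
    rng = np.random.default_rng(seed)
    sub = np.repeat([f"s{i}" for i in range(n_sub)], 3)
    sess = np.tile(["STAND", "HM1", "HM2"], n_sub)
    eff = dict(zip(["STAND", "HM1", "HM2"], contrasts))
    u = np.repeat(rng.normal(0, sd_u, n_sub), 3)
    y = np.array([eff[s] for s in sess]) + u + rng.normal(0, sd_e, 3 * n_sub)
    return pd.DataFrame({outcome: y, "session": sess, "subject_id": sub})


class TestFitLMM:
    def test_noiseless_session_contrasts_exact(self):
        df = make_session_data(30, contrasts=(1.0, 2.0, 3.5), sd_u=0.0, sd_e=0.0)
        res = fit_lmm(df, "y", "session")
        assert res.term("HM1")["estimate"] == pytest.approx(1.0, abs=1e-8)
        assert res.term("HM2")["estimate"] == pytest.approx(2.5, abs=1e-8)
        assert res.resid_var < 1e-10

    def test_zero_group_variance_matches_ols(self):
        df = make_session_data(80, contrasts=(0.0, 0.5, 1.2), sd_u=0.0, sd_e=1.0, seed=4)
        res = fit_lmm(df, "y", "session")
        ols = smf.ols("y ~ C(session, Treatment('STAND'))", df).fit()
        np.testing.assert_allclose(
            res.terms["estimate"].to_numpy(),
            ols.params.to_numpy(),
            atol=1e-6,
        )

    def test_recovers_simulated_effects_and_variances(self):
        df = make_session_data(300, contrasts=(0.0, 1.0, 2.5), sd_u=2.0, sd_e=1.0, seed=9)
        res = fit_lmm(df, "y", "session")
        for term, truth in (("HM1", 1.0), ("HM2", 2.5)):
            t = res.term(term)
            assert abs(t["estimate"] - truth) < 3 * t["se"]
        assert res.group_var == pytest.approx(4.0, rel=0.35)
        assert res.resid_var == pytest.approx(1.0, rel=0.25)
        assert res.n_obs == 900 and res.n_groups == 300

    def test_conditional_r2_exceeds_marginal_with_strong_subject_effects(self):
        df = make_session_data(150, sd_u=3.0, sd_e=0.5, seed=2)
        res = fit_lmm(df, "y", "session")
        assert res.r2_adj_conditional > res.r2_adj_marginal

    def test_continuous_rating_slope(self):
        rng = np.random.default_rng(3)
        n = 200
        sub = np.repeat([f"s{i}" for i in range(n)], 3)
        rating = rng.integers(0, 6, 3 * n)
        y = 0.45 * rating + np.repeat(rng.normal(0, 1, n), 3) + rng.normal(0, 0.5, 3 * n)
        df = pd.DataFrame({"y": y, "rating": rating, "subject_id": sub})
        res = fit_lmm(df, "y", "rating")
        t = res.term("rating")
        assert abs(t["estimate"] - 0.45) < 3 * t["se"]

    def test_single_subject_rejected(self):
        df = make_session_data(1)
        with pytest.raises(FitError, match="2 subjects"):
            fit_lmm(df, "y", "session")

    def test_row_permutation_invariance(self):
        df = make_session_data(60, sd_u=1.5, seed=11)
        res1 = fit_lmm(df, "y", "session")
        res2 = fit_lmm(df.sample(frac=1.0, random_state=1), "y", "session")
        np.testing.assert_allclose(
            res1.terms["estimate"].to_numpy(), res2.terms["estimate"].to_numpy(), atol=1e-8
        )

    def test_subject_relabeling_invariance(self):
        df = make_session_data(60, sd_u=1.5, seed=12)
        relab = df.copy()
        relab["subject_id"] = relab["subject_id"].map(lambda s: f"zz_{s[::-1]}")
        res1 = fit_lmm(df, "y", "session")
        res2 = fit_lmm(relab, "y", "session")
        np.testing.assert_allclose(
            res1.terms["estimate"].to_numpy(), res2.terms["estimate"].to_numpy(), atol=1e-8
        )


class TestBHFDR:
    def test_hand_enumerated_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.5])
        adj, rej = bh_fdr(p, 0.05)
        # step-up: p_(3)=0.03 <= 3*0.05/4=0.0375 -> reject first three
        np.testing.assert_array_equal(rej, [True, True, True, False])

    def test_all_ones(self):
        adj, rej = bh_fdr(np.ones(6), 0.05)
        assert not rej.any()
        np.testing.assert_allclose(adj, 1.0)

    def test_single_pvalue(self):
        adj, rej = bh_fdr([0.04], 0.05)
        assert rej[0] and adj[0] == pytest.approx(0.04)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            m = rng.integers(1, 51)
            p = rng.random(m) ** rng.uniform(0.3, 3.0)
            q = rng.uniform(0.01, 0.2)
            adj, rej = bh_fdr(p, q)
            adj_bf, rej_bf = brute_force_bh(p, q)
            np.testing.assert_allclose(adj, adj_bf, atol=1e-12)
            np.testing.assert_array_equal(rej, rej_bf)

    def test_adjusted_monotone_in_rawp_order(self):
        rng = np.random.default_rng(5)
        p = rng.random(30)
        adj, _ = bh_fdr(p, 0.05)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        for bad in ([0.5, 1.2], [-0.1], [np.nan]):
            with pytest.raises(InputError):
                bh_fdr(bad, 0.05)


@pytest.fixture(scope="module")
def biased_scores():
    rng = np.random.default_rng(31)
    n_sub, k = 80, 6
    sub = np.repeat([f"s{i}" for i in range(n_sub)], 3)
    sess = np.tile(["STAND", "HM1", "HM2"], n_sub)
    sev = {"STAND": 0.0, "HM1": 1.0, "HM2": 2.0}
    scores = rng.normal(size=(3 * n_sub, k)) + np.repeat(
        rng.normal(0, 1, (n_sub, k)), 3, axis=0
    )
    scores[:, 0] += np.array([sev[s] for s in sess])  # bias only in PC1
    ids = [f"{s}_{ses}" for s, ses in zip(sub, sess)]
    sdf = pd.DataFrame(scores, index=pd.Index(ids, name="scan_id"),
                       columns=[f"PC{i+1}" for i in range(k)])
    meta = pd.DataFrame({"scan_id": ids, "subject_id": sub, "session": sess})
    return sdf, meta


class TestPCMotionTests:
    def test_biased_component_rejected_others_mostly_not(self, biased_scores):
        sdf, meta = biased_scores
        rep = pc_motion_tests(sdf, meta, "session", q=0.05)
        assert bool(rep.table.loc["PC1", "rejected"])
        assert rep.table.iloc[1:]["rejected"].sum() <= 1

    def test_q_limits(self, biased_scores):
        sdf, meta = biased_scores
        assert pc_motion_tests(sdf, meta, "session", q=0.999).table["rejected"].all()
        tiny = pc_motion_tests(sdf, meta, "session", q=1e-12)
        assert not tiny.table.iloc[1:]["rejected"].any()

    def test_single_component_reduces_to_raw_p(self, biased_scores):
        sdf, meta = biased_scores
        rep = pc_motion_tests(sdf.iloc[:, [0]], meta, "session", q=0.05)
        row = rep.table.iloc[0]
        for c in ("HM1", "HM2"):
            assert row[f"p_adj_{c}"] == pytest.approx(row[f"p_{c}"], abs=1e-12)

    def test_explained_variance_mass(self, biased_scores):
        sdf, meta = biased_scores
        ev = np.array([0.4, 0.2, 0.15, 0.1, 0.1, 0.05])
        rep = pc_motion_tests(sdf, meta, "session", q=0.05, explained_variance=ev)
        assert rep.explained_variance_rejected["any"] >= 0.4


class TestRaterAgreement:
    def test_identical_ratings(self):
        a = np.array([0, 1, 2, 3, 4, 5, 2, 3])
        res = rater_agreement(a, a.copy())
        assert res.percent_agreement == 100.0
        assert res.kappa == pytest.approx(1.0)

    def test_independent_ratings_kappa_near_zero(self):
        rng = np.random.default_rng(17)
        a = rng.integers(0, 6, 2000)
        b = rng.integers(0, 6, 2000)
        res = rater_agreement(a, b)
        # SE of weighted kappa at n=2000 is roughly 0.015-0.02
        assert abs(res.kappa) < 0.06

    def test_systematic_reversal_negative_kappa(self):
        """3-level toy, hand-checked: reversal gives maximal weighted
        disagreement, kappa < 0."""
        a = np.array([0, 0, 1, 1, 5, 5, 0, 5, 1, 0])
        b = 5 - a
        res = rater_agreement(a, b)
        assert res.kappa < 0

    def test_constant_identical_flagged_undefined(self):
        res = rater_agreement([3, 3, 3], [3, 3, 3])
        assert res.percent_agreement == 100.0
        assert res.kappa is None and res.kappa_undefined

    def test_validation(self):
        with pytest.raises(InputError):
            rater_agreement([0, 1], [0])
        with pytest.raises(InputError):
            rater_agreement([0, 7], [0, 1])
        with pytest.raises(InputError):
            rater_agreement([5], [5])
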