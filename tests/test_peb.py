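import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from sedcm.inversion import PosteriorDensity, PriorDensity
from sedcm.parameters import default_parameters
from sedcm.peb import (
    DesignError,
    DesignMatrix,
    FamilyMask,
    NestingError,
    PEBConfig,
    bayesian_model_reduction,
    build_design_matrix,
    compare_family_models,
    compare_hypotheses,
    enumerate_family_models,
    fit_peb,
)


def cohort_meta(n_resp=8, n_nonresp=9, other_asm=False):
    rows = []
    for g, n, prefix in (("responder", n_resp, "r"), ("nonresponder", n_nonresp, "n")):
        for i in range(n):
            for cond in ("pre", "post"):
                rows.append({"patient_id": f"{prefix}{i + 1:02d}", "group": g,
                             "condition": cond, "other_asm": other_asm})
    return pd.DataFrame(rows)


class TestDesignMatrix:
    def test_paper_cohort_shape_gives_34_rows(self):
        X = build_design_matrix(cohort_meta())
        assert X.values.shape[0] == 34

    def test_interaction_is_elementwise_product(self):
        X = build_design_matrix(cohort_meta(3, 3))
        np.testing.assert_array_equal(
            X.column("resp_x_bzp"), X.column("resp") * X.column("bzp"))

    def test_balanced_effect_coding_sums_to_zero(self):
        X = build_design_matrix(cohort_meta(4, 4))
        assert X.column("resp").sum() == 0
        assert X.column("bzp").sum() == 0
        assert np.all(X.column("intercept") == 1)

    def test_missing_condition_rejected(self):
        meta = cohort_meta(2, 2).iloc[1:]
        with pytest.raises(DesignError, match="pre and a post"):
            build_design_matrix(meta)

    def test_collinear_columns_named(self):
        with pytest.raises(DesignError, match="collinear"):
            DesignMatrix(
                np.column_stack([np.ones(4), [1, -1, 1, -1], [1, -1, 1, -1]]),
                ("intercept", "resp", "bzp"),
                tuple((f"p{i}", "pre") for i in range(4)),
            )


class TestFamilyEnumeration:
    def test_exactly_15_models(self):
        masks = enumerate_family_models()
        assert len(masks) == 15

    def test_all_masks_distinct(self):
        masks = enumerate_family_models()
        seen = {frozenset(m.parameter_names) for m in masks}
        assert len(seen) == 15

    def test_singletons_partition_variable_parameters(self):
        params = default_parameters()
        singles = [m for m in enumerate_family_models() if len(m.name) == 1]
        union = [p for m in singles for p in m.parameter_names]
        assert sorted(union) == sorted(params.variable_names)
        assert len(union) == 14

    def test_invalid_family_letters_rejected(self):
        with pytest.raises(ValueError):
            FamilyMask.from_letters("tx")


def synthetic_first_level(beta, meta, sd_like=0.15, patient_sd=0.05, seed=0,
                          parameter_names=("g_ii_ss", "g_ii_sp", "g_ii_dp", "tau_ii")):
    """First-level posteriors drawn from a known linear-Gaussian hierarchy.

    beta: {regressor: {parameter: effect}} in the effect-coded basis.
    The 'posterior' for each model is an exact Bayesian update of the
    first-level prior with a Gaussian likelihood of sd ``sd_like`` centered
    on a noisy measurement of the true parameter vector.
    """
    rng = np.random.default_rng(seed)
    p = len(parameter_names)
    fl_prior = PriorDensity(parameter_names, np.zeros(p), np.eye(p) * 0.125)
    X = build_design_matrix(meta)
    posts = []
    patient_dev = {}
    for k, (pid, cond) in enumerate(X.rows):
        if pid not in patient_dev:
            patient_dev[pid] = rng.normal(0, patient_sd, p)
        x = X.values[k]
        theta = patient_dev[pid].copy()
        for j, par in enumerate(parameter_names):
            for c, col in enumerate(X.columns):
                theta[j] += beta.get(col, {}).get(par, 0.0) * x[c]
        y = theta + rng.normal(0, sd_like, p)
        lam = 1.0 / sd_like**2
        P = lam * np.eye(p) + np.linalg.inv(fl_prior.cov)
        C = np.linalg.inv(P)
        mu = C @ (lam * y)
        posts.append(PosteriorDensity(parameter_names, mu, C, 0.0))
    return posts, fl_prior, X


class TestFitPEB:
    def test_single_model_intercept_only_reproduces_first_level_posterior(self):
        names = ("g_ii_ss", "g_ii_dp")
        fl_prior = PriorDensity(names, np.zeros(2), np.eye(2) * 0.125)
        post = PosteriorDensity(names, np.array([0.3, -0.1]),
                                np.eye(2) * 0.01, 0.0)
        X = DesignMatrix(np.ones((1, 1)), ("intercept",), (("p1", "pre"),))
        res = fit_peb([post], X, parameter_names=names, first_level_prior=fl_prior)
        np.testing.assert_allclose(res.beta[0], post.mean, atol=1e-2)

    def test_recovers_known_group_effect(self):
        beta = {"resp": {"g_ii_ss": -0.3}}
        posts, fl_prior, X = synthetic_first_level(beta, cohort_meta(8, 9), seed=1)
        res = fit_peb(posts, X, parameter_names=posts[0].names,
                      first_level_prior=fl_prior)
        m, sd = res.effect("resp", "g_ii_ss")
        assert abs(m - (-0.3)) < 2 * sd

    def test_inflating_first_level_variance_widens_beta_posterior(self):
        beta = {"resp": {"g_ii_ss": -0.3}}
        posts, fl_prior, X = synthetic_first_level(beta, cohort_meta(4, 4), seed=2)
        res1 = fit_peb(posts, X, parameter_names=posts[0].names, first_level_prior=fl_prior)
        wider = [PosteriorDensity(p.names, p.mean, p.cov * 3.0, 0.0) for p in posts]
        res2 = fit_peb(wider, X, parameter_names=posts[0].names, first_level_prior=fl_prior)
        _, sd1 = res1.effect("resp", "g_ii_ss")
        _, sd2 = res2.effect("resp", "g_ii_ss")
        assert sd2 > sd1

    def test_row_count_mismatch_rejected(self):
        posts, fl_prior, X = synthetic_first_level({}, cohort_meta(2, 2))
        with pytest.raises(DesignError, match="design rows"):
            fit_peb(posts[:-1], X, parameter_names=posts[0].names,
                    first_level_prior=fl_prior)


class TestBayesianModelReduction:
    def setup_method(self):
        rng = np.random.default_rng(5)
        self.prior = PriorDensity(("a", "b"), np.zeros(2), np.diag([1.0, 2.0]))
        self.lam = 1.0
        self.y = rng.normal([2.0, -0.3], 0.1)
        Sig = np.exp(-self.lam) * np.eye(2)
        P = np.linalg.inv(Sig) + np.linalg.inv(self.prior.cov)
        C = np.linalg.inv(P)
        mu = C @ np.linalg.solve(Sig, self.y)
        F = multivariate_normal.logpdf(self.y, self.prior.mean, self.prior.cov + Sig)
        self.post = PosteriorDensity(("a", "b"), mu, C, F)
        self.Sig = Sig

    def test_identity_reduction_is_exact_zero(self):
        dF, post = bayesian_model_reduction(self.post, self.prior, self.prior)
        assert dF == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(post.mean, self.post.mean, atol=1e-10)

    def test_matches_directly_computed_log_evidences(self):
        reduced = self.prior.with_entries(variances={"a": 1e-8})
        dF, _ = bayesian_model_reduction(self.post, self.prior, reduced)
        F_red = multivariate_normal.logpdf(self.y, reduced.mean, reduced.cov + self.Sig)
        F_full = self.post.free_energy
        assert dF == pytest.approx(F_red - F_full, abs=1e-6)

    def test_pruning_a_strong_effect_loses_evidence(self):
        reduced = self.prior.with_entries(variances={"a": 1e-8})
        dF, _ = bayesian_model_reduction(self.post, self.prior, reduced)
        assert dF < 0

    def test_non_nested_prior_rejected(self):
        inflated = self.prior.with_entries(variances={"a": 5.0})
        with pytest.raises(NestingError):
            bayesian_model_reduction(self.post, self.prior, inflated)


class TestHypothesisAndFamilyComparison:
    def make_structured(self, seed=0):
        beta = {
            "resp": {"g_ii_ss": -0.25, "g_ii_sp": -0.2},
            "bzp": {"g_ii_ss": 0.3, "g_ii_sp": 0.25},
            "resp_x_bzp": {"g_ii_ss": 0.25, "g_ii_dp": -0.15},
        }
        meta = cohort_meta(8, 9)
        posts, fl_prior, _ = synthetic_first_level(beta, meta, seed=seed)
        return posts, fl_prior, meta

    def test_full_structure_wins_on_structured_cohort(self):
        posts, fl_prior, meta = self.make_structured(seed=3)
        res = compare_hypotheses(posts, meta, parameter_names=posts[0].names,
                                 first_level_prior=fl_prior)
        assert res["winner"] == "H3"
        assert res["decisive"]

    def test_inhibitory_family_wins_when_effects_are_inhibitory(self):
        posts, fl_prior, meta = self.make_structured(seed=4)
        res = compare_family_models(posts, meta, parameter_names=posts[0].names,
                                    first_level_prior=fl_prior)
        assert len(res["table"]) == 15
        assert res["winner"] == "i"

    def test_effect_directions_match_generation(self):
        posts, fl_prior, meta = self.make_structured(seed=5)
        res = compare_hypotheses(posts, meta, parameter_names=posts[0].names,
                                 first_level_prior=fl_prior)
        full = res["full"]
        assert full.effect("resp", "g_ii_ss")[0] < 0
        assert full.effect("bzp", "g_ii_ss")[0] > 0
        assert full.effect("resp_x_bzp", "g_ii_ss")[0] > 0
        assert full.effect("resp_x_bzp", "g_ii_dp")[0] < 0

    def test_comparison_invariant_to_model_order(self):
        posts, fl_prior, meta = self.make_structured(seed=6)
        res1 = compare_family_models(posts, meta, parameter_names=posts[0].names,
                                     first_level_prior=fl_prior)
        perm = np.random.default_rng(0).permutation(len(posts))
        meta2 = meta.iloc[perm].reset_index(drop=True)
        posts2 = [posts[i] for i in perm]
        res2 = compare_family_models(posts2, meta2, parameter_names=posts[0].names,
                                     first_level_prior=fl_prior)
        t1 = res1["table"].set_index("family").free_energy
        t2 = res2["table"].set_index("family").free_energy
        # the random-effects variance optimizer introduces tiny
        # order-dependent numerical differences; rankings must agree
        np.testing.assert_allclose(t1.sort_index(), t2.sort_index(), atol=0.5)
        assert res1["winner"] == res2["winner"]

    def test_repeated_evaluation_is_deterministic(self):
        posts, fl_prior, meta = self.make_structured(seed=7)
        a = compare_hypotheses(posts, meta, parameter_names=posts[0].names,
                               first_level_prior=fl_prior)
        b = compare_hypotheses(posts, meta, parameter_names=posts[0].names,
                               first_level_prior=fl_prior)
        assert a["free_energy"] == b["free_energy"]

    def test_null_cohort_has_no_decisive_winner(self):
        meta = cohort_meta(8, 9)
        posts, fl_prior, _ = synthetic_first_level({}, meta, seed=8)
        hyp = compare_hypotheses(posts, meta, parameter_names=posts[0].names,
                                 first_level_prior=fl_prior)
        fam = compare_family_models(posts, meta, parameter_names=posts[0].names,
                                    first_level_prior=fl_prior)
        assert not hyp["decisive"]
        assert not fam["decisive"]
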