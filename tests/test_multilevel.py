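"""Model fitting, effect testing, prediction and outlier handling."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from atlascomp import multilevel as ml
from atlascomp import synthetic_atlas as sa
from atlascomp._posterior import CompositionPosterior, PriorConfig
from atlascomp.compositional import sum_to_zero_basis
from atlascomp.containers import CompositionMatrix
from atlascomp.design import DesignSpec, build_design
from conftest import make_recovery_setup, quick_fit


def test_symmetric_counts_give_symmetric_posterior():
    counts = CompositionMatrix(pd.DataFrame(
        {"a": [50] * 20, "b": [50] * 20},
        index=[f"s{i}" for i in range(20)]))
    samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(20)]})
    design = build_design(samples, DesignSpec(fixed_terms=["intercept"],
                                              random_terms=[]))
    fit = quick_fit(counts, design, seed=0)
    pred = ml.predict_composition(fit, pd.DataFrame(index=[0]))
    assert 0.45 < pred.iloc[0, 0] < 0.55
    assert 0.45 < pred.iloc[0, 1] < 0.55


def test_sum_to_zero_holds_exactly_on_every_draw(small_fit):
    np.testing.assert_allclose(small_fit.beta.sum(axis=2), 0.0, atol=1e-10)
    np.testing.assert_allclose(small_fit.gamma.sum(axis=2), 0.0, atol=1e-10)
    for u in small_fit.u.values():
        np.testing.assert_allclose(u.sum(axis=3), 0.0, atol=1e-10)


def test_softmax_invariance_of_predictions(small_fit, small_atlas):
    """Adding a constant across categories to eta leaves proportions fixed."""
    from atlascomp.compositional import softmax
    eta = ml.posterior_eta(small_fit,
                           small_fit.design.X[:3])[:50]
    p1 = softmax(eta, axis=2)
    p2 = softmax(eta + 3.7, axis=2)
    np.testing.assert_allclose(p1, p2, atol=1e-10)


def test_counts_must_align_with_design(small_atlas):
    design = build_design(small_atlas["samples"].iloc[:5], DesignSpec())
    with pytest.raises(ValueError, match="align"):
        ml.fit(small_atlas["counts"], design)


def test_non_integer_counts_rejected(small_atlas):
    bad = CompositionMatrix(small_atlas["counts"].counts + 0.5)
    design = build_design(small_atlas["samples"], DesignSpec())
    with pytest.raises(ValueError, match="integer"):
        ml.fit(bad, design)


class TestEffectTesting:
    def test_fdr_hand_example(self):
        np.testing.assert_allclose(
            ml.fdr_from_prob_null(np.array([0.01, 0.02, 0.10])),
            [0.01, 0.015, 0.04333333333], atol=1e-9)

    def test_fdr_sequence_non_decreasing_along_ranking(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(15)
            fdr = ml.fdr_from_prob_null(p)
            order = np.argsort(p, kind="stable")
            assert np.all(np.diff(fdr[order]) >= -1e-12)

    def test_zero_effect_draws_give_prob_null_one(self, small_fit):
        import copy
        fit = copy.copy(small_fit)
        fit.beta = np.zeros_like(fit.beta)
        eff = ml.test_effects(fit, "age_scaled", "body")
        assert (eff["prob_null"] == 1.0).all()
        assert not eff["significant"].any()

    def test_other_immune_reported_but_never_significant(self, small_atlas):
        counts = small_atlas["counts"].counts.copy()
        counts = counts.rename(columns={"type_3": "other immune"})
        design = build_design(small_atlas["samples"], DesignSpec())
        fit = quick_fit(CompositionMatrix(counts), design,
                        seed=small_atlas["seed"])
        eff = ml.test_effects(fit, "age_scaled", "body", fdr_threshold=1.1)
        oi = eff[eff["category"] == "other immune"]
        assert len(oi) == 1
        assert not oi["significant"].iloc[0]
        assert np.isnan(oi["fdr"].iloc[0])
        # every other category is significant at this absurd threshold
        assert eff[eff["category"] != "other immune"]["significant"].all()

    def test_tissue_level_adds_group_effect(self, small_fit):
        body = ml.test_effects(small_fit, "age_scaled", "body")
        tis = ml.test_effects(small_fit, "age_scaled", "tissue:tissue_00")
        assert not np.allclose(body["posterior_mean"], tis["posterior_mean"])

    def test_unknown_tissue_rejected(self, small_fit):
        with pytest.raises(KeyError, match="mystery"):
            ml.test_effects(small_fit, "age_scaled", "tissue:mystery")

    def test_unknown_contrast_rejected(self, small_fit):
        with pytest.raises(KeyError, match="not in fitted design"):
            ml.test_effects(small_fit, "nope", "body")


class TestSignedFoldChange:
    def test_definition_on_synthetic_proportions(self):
        p_lo, p_hi = 0.1, 0.2
        assert p_hi / p_lo == pytest.approx(2.0)
        fc = np.where(p_hi >= p_lo, p_hi / p_lo, -(p_lo / p_hi))
        assert fc == pytest.approx(2.0)

    def test_equal_proportions_give_unit_fold_change(self, small_fit):
        fc = ml.signed_fold_change(small_fit, "age_scaled", (0.3, 0.3))
        np.testing.assert_allclose(fc.to_numpy(), 1.0)

    def test_sign_matches_generating_slope(self):
        samples, truth, counts, design = make_recovery_setup(21, slope=1.0)
        fit = quick_fit(counts, design, seed=21)
        lo = samples["age_scaled"].min()
        hi = samples["age_scaled"].max()
        fc = ml.signed_fold_change(fit, "age_scaled", (lo, hi))
        strong = np.abs(truth.beta[1]) > 0.5
        assert np.all(np.sign(fc.to_numpy()[strong])
                      == np.sign(truth.beta[1][strong]))

    def test_out_of_support_range_warns(self, small_fit):
        with pytest.warns(UserWarning, match="outside observed support"):
            ml.signed_fold_change(small_fit, "age_scaled", (-100.0, 100.0))


class TestPrediction:
    def test_rows_sum_to_one(self, small_fit, small_atlas):
        pred = ml.predict_composition(small_fit, small_atlas["samples"])
        np.testing.assert_allclose(pred.sum(axis=1), 1.0, atol=1e-8)

    def test_intercept_only_fit_predicts_baseline_everywhere(self):
        counts = CompositionMatrix(pd.DataFrame(
            {"a": [30] * 10, "b": [60] * 10, "c": [10] * 10},
            index=[f"s{i}" for i in range(10)]))
        samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(10)],
                                "age_scaled": np.linspace(-1, 1, 10)})
        design = build_design(samples, DesignSpec(fixed_terms=["intercept"],
                                                  random_terms=[]))
        fit = quick_fit(counts, design, seed=1)
        pred = ml.predict_composition(
            fit, pd.DataFrame({"age_scaled": [-5.0, 5.0]}))
        np.testing.assert_allclose(pred.iloc[0], pred.iloc[1], atol=1e-12)

    def test_predictions_track_observed_proportions(self):
        samples, truth, counts, design = make_recovery_setup(13)
        fit = quick_fit(counts, design, seed=13)
        pred = ml.predict_composition(
            fit, samples, include_groups=list(design.groups))
        obs = counts.values() / counts.totals[:, None]
        rho = scipy.stats.spearmanr(pred.to_numpy().ravel(),
                                    obs.ravel()).statistic
        assert rho >= 0.8

    def test_unseen_group_level_rejected(self, small_fit):
        rows = pd.DataFrame({"age_scaled": [0.0],
                             "tissue_harmonised": ["not-a-tissue"]})
        with pytest.raises(KeyError, match="not seen in training"):
            ml.predict_composition(small_fit, rows,
                                   include_groups=["tissue_harmonised"])


class TestOutliers:
    def test_flags_deterministic_given_fit_and_counts(self, small_fit,
                                                      small_atlas):
        f1 = ml.identify_outliers(small_fit, small_atlas["counts"], 0.95)
        f2 = ml.identify_outliers(small_fit, small_atlas["counts"], 0.95)
        pd.testing.assert_frame_equal(f1, f2)

    def test_invalid_ppc_level_rejected(self, small_fit, small_atlas):
        with pytest.raises(ValueError):
            ml.identify_outliers(small_fit, small_atlas["counts"], 1.5)

    def test_null_data_flagging_within_calibration_bound(self, small_fit,
                                                         small_atlas):
        flags = ml.identify_outliers(small_fit, small_atlas["counts"], 0.95)
        assert flags.to_numpy().mean() <= 2 * (1 - 0.95)


def test_zero_group_variance_matches_single_level_fit():
    """With no true group-level variation the partially pooled fit agrees
    with a single-level fit within Monte-Carlo error."""
    seed = 5
    samples, truth, counts, _ = make_recovery_setup(
        seed, n_tissues=6, samples_per_dataset=15,
        tissue_intercept_sd=0.0, tissue_slope_sd=0.0, dataset_sd=0.0)
    fit_ml = quick_fit(counts, build_design(samples, DesignSpec()), seed=seed)
    fit_sl = quick_fit(counts,
                       build_design(samples, DesignSpec(random_terms=[])),
                       seed=seed)
    np.testing.assert_allclose(fit_ml.beta[:, 1, :].mean(axis=0),
                               fit_sl.beta[:, 1, :].mean(axis=0), atol=0.05)


def test_hmc_agrees_with_laplace_on_small_model():
    cfg = sa.AtlasConfig(n_tissues=2, datasets_per_tissue=1,
                         samples_per_dataset=15, n_categories=3,
                         cells_per_sample_range=(200, 400))
    samples = sa.generate_sample_frame(cfg, 7)
    truth = sa.GroundTruth.random(3, 2, 2, seed=7)
    counts = sa.generate_counts(samples, truth, DesignSpec(), 7,
                                categories=cfg.categories())
    design = build_design(samples, DesignSpec())
    fit_h = ml.fit(counts, design, options=ml.FitOptions(
        method="hmc", seed=7, draws=300, warmup=500, chains=2))
    fit_l = quick_fit(counts, design, seed=7)
    np.testing.assert_allclose(fit_h.beta[:, 1, :].mean(axis=0),
                               fit_l.beta[:, 1, :].mean(axis=0), atol=0.15)
    assert fit_h.diagnostics["divergences"] >= 0
    assert np.isfinite(fit_h.diagnostics["max_rhat"])


def test_rhat_reported_for_all_parameters(small_fit):
    assert small_fit.diagnostics["rhat"].shape[0] == small_fit.mode.size


def test_posterior_gradient_matches_finite_differences(small_atlas):
    design = build_design(small_atlas["samples"], DesignSpec())
    post = CompositionPosterior(small_atlas["counts"].counts.to_numpy(),
                                design)
    rng = np.random.default_rng(0)
    x = post.initial_point(rng, jitter=0.1)
    _, g = post.log_posterior(x)
    for i in rng.choice(x.size, 20, replace=False):
        h = 1e-6 * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        fd = (post.log_posterior(xp)[0] - post.log_posterior(xm)[0]) / (2 * h)
        assert abs(fd - g[i]) <= 1e-4 * max(1.0, abs(fd))


def test_simulation_based_calibration_ranks_uniform():
    """Rank statistics of true age slopes within posterior draws are
    approximately uniform across 50 prior-draw replicates (K=4, 50 samples)."""
    K, S = 4, 50
    Q = sum_to_zero_basis(K)
    priors = PriorConfig(beta_sd=1.0, gamma_sd=0.3, gamma_base_mean=4.0,
                         gamma_base_sd=0.5, use_association=False)
    spec = DesignSpec(random_terms=[])
    ranks = []
    for rep in range(50):
        rng = np.random.default_rng(1000 + rep)
        beta = rng.normal(0, 1.0, (2, K - 1)) @ Q.T
        gamma = rng.normal(0, 0.3, (1, K - 1)) @ Q.T
        gb = rng.normal(4.0, 0.5, 1)
        samples = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(S)],
            "age_scaled": rng.normal(0, 1, S),
            "n_cells": rng.integers(200, 800, S)})
        truth = sa.GroundTruth(beta=beta, u_tissue=np.zeros((1, 2, K)),
                               v_dataset=np.zeros((1, K)), gamma=gamma,
                               gamma_base=gb)
        counts = sa.generate_counts(samples, truth, spec, 2000 + rep)
        fit = ml.fit(counts, build_design(samples, spec),
                     options=ml.FitOptions(seed=3000 + rep, draws=63,
                                           chains=4, priors=priors))
        ranks.append(int((fit.beta[:, 1, 0] < beta[1, 0]).sum()))
    hist, _ = np.histogram(ranks, bins=np.linspace(0, 252, 10))
    expected = 50 / 9
    chi2 = ((hist - expected) ** 2 / expected).sum()
    p = scipy.stats.chi2.sf(chi2, 8)
    assert p > 0.01
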