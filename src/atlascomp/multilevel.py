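"""Fitting, testing and predicting with the multilevel compositional model.

Hypothesis testing follows the body/tissue split: body-level claims test the
population-level coefficient alone; tissue-level claims test the sum of the
population-level and that tissue's group-level coefficient. Significance is
called through the posterior-probability false-discovery rate: categories
are ranked by the posterior mass inside an interval null |theta| <
null_halfwidth, and the FDR at rank i is the mean of the i smallest null
probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import betabinom as _betabinom

from . import inference
from ._posterior import CompositionPosterior, PriorConfig
from .compositional import softmax
from .containers import CompositionMatrix
from .design import Design, DesignSpec, build_design
from .harmonise import OTHER_IMMUNE


@dataclass
class FitOptions:
    method: str = "laplace"          # "laplace" (fast, approximate) or "hmc"
    chains: int = 4
    draws: int = 1000                # per chain
    warmup: int = 400                # hmc only
    seed: int = 0
    maxiter: int = 2000
    priors: PriorConfig = field(default_factory=PriorConfig)
    outlier_passes: int = 1          # 1 = no outlier-exclusion refit
    ppc_level: float = 0.95          # reporting level for outlier flags
    # only decisively incompatible observations are excluded before a refit;
    # excluding merely borderline ones truncates the distribution and biases
    # the refitted coefficients
    exclusion_level: float = 0.995
    rhat_warn: float = 1.05


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class ModelFit:
    """Posterior draws plus diagnostics for one fitted model.

    Draw arrays carry the sum-to-zero constraint across categories exactly
    (they are linear images of the free parametrisation). ``gamma`` holds
    the centred category-specific log-precision coefficients and
    ``gamma_base`` the category-wide baseline per variability covariate.
    """

    design: Design
    categories: list[str]
    beta: np.ndarray                   # (N, P, K)
    u: dict[str, np.ndarray]           # group -> (N, L, T, K)
    gamma: np.ndarray                  # (N, Pv, K)
    gamma_base: np.ndarray             # (N, Pv)
    sigma: dict[str, np.ndarray]       # group -> (N, T)
    assoc: np.ndarray                  # (N, 3): c0, c1, tau
    mode: np.ndarray
    diagnostics: dict
    options: FitOptions
    outlier_flags: pd.DataFrame | None = None
    counts_fingerprint: str = ""

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def fixed_index(self, name: str) -> int:
        return self.design.x_names.index(name)


def _split_rhat(chains: np.ndarray) -> float:
    """Split-Rhat of a (chains, draws) array."""
    c, d = chains.shape
    half = d // 2
    if half < 2:
        return np.nan
    parts = chains[:, : 2 * half].reshape(c * 2, half)
    w = parts.var(axis=1, ddof=1).mean()
    b = half * parts.mean(axis=1).var(ddof=1)
    if w <= 0:
        return 1.0
    return float(np.sqrt((w * (half - 1) / half + b / half) / w))


def _diagnose(result: inference.InferenceResult, layout) -> dict:
    draws = result.draws                        # (C, D, dim)
    rhats = np.array([_split_rhat(draws[:, :, j]) for j in range(draws.shape[2])])
    with np.errstate(invalid="ignore"):
        max_rhat = float(np.nanmax(rhats)) if rhats.size else np.nan
    return {
        "rhat": rhats,
        "max_rhat": max_rhat,
        "divergences": result.diagnostics.get("divergences", 0),
        "ess": float(draws.shape[0] * draws.shape[1]),
        "method": result.method,
    }


def fit(counts: CompositionMatrix, design: Design | DesignSpec,
        samples: pd.DataFrame | None = None,
        options: FitOptions | None = None,
        mask: np.ndarray | None = None) -> ModelFit:
    """Fit the multilevel beta-binomial compositional model.

    With ``options.outlier_passes > 1``, observations falling outside the
    central ``ppc_level`` posterior-predictive interval are excluded and the
    model refitted (at most ``outlier_passes`` passes), making the final
    estimates outlier-insensitive.
    """
    options = options or FitOptions()
    if isinstance(design, DesignSpec):
        if samples is None:
            raise ValueError("samples table required to build the design")
        design = build_design(samples, design)
    y = counts.counts.to_numpy()
    if design.X.shape[0] != y.shape[0]:
        raise ValueError("counts rows must align with design rows")

    current = _fit_once(y, design, options, mask, counts.categories)
    flags = None
    for _ in range(options.outlier_passes - 1):
        exclude = identify_outliers(current, counts, options.exclusion_level)
        keep = ~exclude.to_numpy()
        if mask is not None:
            keep &= mask
        if keep.all():
            break
        current = _fit_once(y, design, options, keep, counts.categories)
    if options.outlier_passes > 1:
        # report flags against the cleaned refit: the first-pass dispersion
        # is inflated by the very outliers being hunted
        flags = identify_outliers(current, counts, options.ppc_level)
    current.outlier_flags = flags
    current.counts_fingerprint = str(abs(hash(y.tobytes())))
    return current


def _fit_once(y: np.ndarray, design: Design, options: FitOptions,
              mask: np.ndarray | None,
              categories: list[str] | None = None) -> ModelFit:
    post = CompositionPosterior(y, design, options.priors, mask=mask)
    rng = np.random.default_rng(options.seed)
    x0 = post.initial_point(rng, jitter=1e-3)
    if options.method == "laplace":
        result = inference.laplace(post.neg_log_posterior, x0,
                                   n_draws=options.draws, rng=rng,
                                   n_chains=options.chains,
                                   maxiter=options.maxiter)
    elif options.method == "hmc":
        result = inference.hmc(post.neg_log_posterior, x0,
                               n_draws=options.draws, rng=rng,
                               n_chains=options.chains,
                               warmup=options.warmup,
                               maxiter=options.maxiter)
    else:
        raise ValueError(f"unknown method {options.method!r}")

    lo, Q = post.layout, post.Q
    flat = result.flat_draws
    beta = lo.beta_free(flat) @ Q.T
    sigma_draws = {name: np.exp(lo.log_sigma(flat, name))
                   for name, _, _ in lo.groups}
    # non-centred group coefficients: u = sigma * u_raw, constrained via Q
    u = {name: (lo.u_free(flat, name) @ Q.T)
         * sigma_draws[name][:, None, :, None]
         for name, _, _ in lo.groups}
    gamma = lo.gamma_free(flat) @ Q.T
    gamma_base = lo.gamma_base(flat)
    sigma = sigma_draws
    assoc = lo.assoc(flat).copy()
    assoc[:, 2] = np.exp(assoc[:, 2])

    diagnostics = _diagnose(result, lo)
    diagnostics["warnings"] = []
    if np.isfinite(diagnostics["max_rhat"]) and \
            diagnostics["max_rhat"] > options.rhat_warn:
        msg = (f"max split-Rhat {diagnostics['max_rhat']:.3f} exceeds "
               f"{options.rhat_warn}; estimates may be unreliable")
        diagnostics["warnings"].append(msg)
        warnings.warn(msg, ConvergenceWarning)

    categories = categories or [f"cat_{k}" for k in range(y.shape[1])]
    return ModelFit(design=design, categories=categories, beta=beta, u=u,
                    gamma=gamma, gamma_base=gamma_base, sigma=sigma,
                    assoc=assoc, mode=result.mode, diagnostics=diagnostics,
                    options=options)


# ---------------------------------------------------------------------------
# posterior predictive outlier detection
# ---------------------------------------------------------------------------

def identify_outliers(fit_: ModelFit, counts: CompositionMatrix,
                      ppc_level: float = 0.95,
                      n_param_draws: int = 50) -> pd.DataFrame:
    """Flag counts in the tails of the posterior-predictive distribution.

    The beta-binomial predictive CDF is evaluated analytically at each
    observed count under the posterior-mean linear predictors (the plug-in
    predictive), with a mid-probability correction for discreteness; an
    observation is flagged when either tail probability falls below
    (1 - ppc_level) / 2. Deterministic given the fit draws and counts.
    """
    if not 0.0 < ppc_level < 1.0:
        raise ValueError("ppc_level must lie in (0, 1)")
    y = counts.counts.to_numpy()
    n = y.sum(axis=1)
    step = max(1, fit_.n_draws // n_param_draws)
    idx = range(0, fit_.n_draws, step)
    eta = np.mean([_eta_for_draw(fit_, i)[0] for i in idx], axis=0)
    log_phi = np.mean([_eta_for_draw(fit_, i)[1] for i in idx], axis=0)
    mu = np.clip(softmax(eta, axis=1), 1e-10, 1 - 1e-10)
    phi = np.exp(np.clip(log_phi, -30, 30))
    a, b = mu * phi, (1 - mu) * phi
    nn = n[:, None].astype(int)
    cdf_at = _betabinom.cdf(y, nn, a, b)
    pmf_at = np.exp(_betabinom.logpmf(y, nn, a, b))
    pit = cdf_at - 0.5 * pmf_at                 # mid-probability PIT
    alpha = (1.0 - ppc_level) / 2.0
    flags = (pit < alpha) | (pit > 1.0 - alpha)
    return pd.DataFrame(flags, index=counts.counts.index,
                        columns=counts.counts.columns)


def _eta_for_draw(fit_: ModelFit, i: int) -> tuple[np.ndarray, np.ndarray]:
    d = fit_.design
    eta = d.X @ fit_.beta[i]
    for g in d.groups.values():
        U = fit_.u[g.name][i]
        eta += np.einsum("nt,ntk->nk", g.slopes, U[g.index])
    log_phi = d.Xv @ (fit_.gamma_base[i][:, None] + fit_.gamma[i])
    return eta, log_phi


def posterior_eta(fit_: ModelFit, X: np.ndarray,
                  group_rows: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
                  ) -> np.ndarray:
    """eta draws (N, rows, K) for arbitrary fixed rows + group assignments."""
    eta = np.einsum("rp,npk->nrk", X, fit_.beta)
    for name, (index, slopes) in (group_rows or {}).items():
        U = fit_.u[name][:, index]              # (N, rows, T, K)
        eta += np.einsum("rt,nrtk->nrk", slopes, U)
    return eta


# ---------------------------------------------------------------------------
# effect testing
# ---------------------------------------------------------------------------

def _resolve_contrast(fit_: ModelFit, contrast) -> dict[str, float]:
    if isinstance(contrast, str):
        contrast = {contrast: 1.0}
    for name in contrast:
        if name not in fit_.design.x_names:
            raise KeyError(f"contrast term {name!r} not in fitted design "
                           f"columns {fit_.design.x_names}")
    return dict(contrast)


def _effect_draws(fit_: ModelFit, contrast: dict[str, float],
                  tissue: str | None, group_name: str) -> np.ndarray:
    theta = np.zeros((fit_.n_draws, len(fit_.categories)))
    for name, w in contrast.items():
        theta += w * fit_.beta[:, fit_.fixed_index(name), :]
    if tissue is not None:
        g = fit_.design.groups.get(group_name)
        if g is None or tissue not in g.levels:
            raise KeyError(f"unknown tissue level {tissue!r}")
        li = g.levels.index(tissue)
        for name, w in contrast.items():
            if name in g.term_names:
                ti = g.term_names.index(name)
                theta += w * fit_.u[group_name][:, li, ti, :]
    return theta


def fdr_from_prob_null(prob_null: np.ndarray) -> np.ndarray:
    """Cumulative mean of sorted posterior null probabilities.

    FDR at rank i is the mean of the i smallest prob_null values; the
    resulting sequence is non-decreasing along the ranking.
    """
    order = np.argsort(prob_null, kind="stable")
    sorted_p = prob_null[order]
    cummean = np.cumsum(sorted_p) / np.arange(1, len(sorted_p) + 1)
    fdr = np.empty_like(cummean)
    fdr[order] = cummean
    return fdr


def test_effects(fit_: ModelFit, contrast, level: str = "body",
                 null_halfwidth: float = 0.2, fdr_threshold: float = 0.05,
                 group_name: str | None = None) -> pd.DataFrame:
    """Posterior interval-null tests per category at body or tissue level.

    ``level`` is ``"body"``, ``"tissue:<name>"`` for one tissue, or
    ``"tissue"`` for every fitted tissue. The ``"other immune"`` category is
    reported but never flagged significant and does not enter the FDR
    ranking.
    """
    contrast = _resolve_contrast(fit_, contrast)
    group_name = group_name or _default_tissue_group(fit_)
    if level == "body":
        tissues = [None]
    elif level == "tissue":
        tissues = list(fit_.design.groups[group_name].levels)
    elif level.startswith("tissue:"):
        tissues = [level.split(":", 1)[1]]
    else:
        raise ValueError(f"unknown level {level!r}")

    rows = []
    for tissue in tissues:
        theta = _effect_draws(fit_, contrast, tissue, group_name)
        prob_null = np.mean(np.abs(theta) < null_halfwidth, axis=0)
        testable = np.array([c != OTHER_IMMUNE for c in fit_.categories])
        fdr = np.full(len(fit_.categories), np.nan)
        if testable.any():
            fdr[testable] = fdr_from_prob_null(prob_null[testable])
        mean = theta.mean(axis=0)
        lo = np.quantile(theta, 0.025, axis=0)
        hi = np.quantile(theta, 0.975, axis=0)
        for k, cat in enumerate(fit_.categories):
            rows.append({
                "category": cat,
                "level": "body" if tissue is None else f"tissue:{tissue}",
                "contrast": "+".join(f"{w:g}*{n}" for n, w in contrast.items()),
                "posterior_mean": mean[k],
                "ci_lower": lo[k],
                "ci_upper": hi[k],
                "prob_null": prob_null[k],
                "fdr": fdr[k],
                "significant": bool(testable[k] and np.isfinite(fdr[k])
                                    and fdr[k] < fdr_threshold),
            })
    return pd.DataFrame(rows)


def _default_tissue_group(fit_: ModelFit) -> str | None:
    for name in fit_.design.groups:
        if "tissue" in name:
            return name
    return next(iter(fit_.design.groups), None)


# ---------------------------------------------------------------------------
# prediction and fold changes
# ---------------------------------------------------------------------------

def predict_composition(fit_: ModelFit, new_rows: pd.DataFrame,
                        include_groups: list[str] | None = None,
                        ) -> pd.DataFrame:
    """Posterior-mean expected proportions for new covariate rows.

    ``include_groups`` selects which random terms contribute (tissue-level
    trajectories include the tissue effects; body-level predictions exclude
    all groups). Rows of the output sum to one.
    """
    X = fit_.design.encode_rows(new_rows)
    group_rows = {}
    for name in include_groups or []:
        g = fit_.design.groups[name]
        vals = new_rows[name].astype(str) if name in new_rows.columns else None
        if vals is None:
            raise KeyError(f"new rows lack grouping column {name!r}")
        unseen = set(vals) - set(g.levels)
        if unseen:
            raise KeyError(f"grouping level(s) {sorted(unseen)} of {name!r} "
                           "not seen in training")
        index = np.array([g.levels.index(v) for v in vals])
        slopes = _encode_group_slopes(fit_.design, name, new_rows)
        group_rows[name] = (index, slopes)
    eta = posterior_eta(fit_, X, group_rows)
    p = softmax(eta, axis=2).mean(axis=0)
    return pd.DataFrame(p, index=new_rows.index, columns=fit_.categories)


def _encode_group_slopes(design: Design, name: str,
                         rows: pd.DataFrame) -> np.ndarray:
    from .design import _encode_term

    spec = design.metadata["spec"]
    slope_terms = dict(spec.random_terms)[name]
    blocks = []
    for term in slope_terms:
        block, _ = _encode_term(term, rows.reset_index(drop=True),
                                design.metadata["baselines"], design.levels,
                                design.metadata.get("intercept_free"),
                                strict=True, defaults=True)
        blocks.append(block)
    return np.column_stack(blocks)


def signed_fold_change(fit_: ModelFit, covariate: str,
                       covariate_range: tuple[float, float],
                       level: str = "body",
                       group_name: str | None = None) -> pd.Series:
    """Signed ratio of predicted proportions at the two range limits.

    FC = p_hi / p_lo when the category increases over the range, else
    -(p_lo / p_hi); all other covariates sit at baseline/reference.
    """
    lo_v, hi_v = covariate_range
    obs = fit_.design.metadata.get("ranges", {}).get(covariate)
    if obs is not None and (lo_v < obs[0] or hi_v > obs[1]):
        warnings.warn(f"range {covariate_range} outside observed support "
                      f"{obs} of {covariate!r}", UserWarning)
    group_name = group_name or _default_tissue_group(fit_)
    rows = pd.DataFrame({covariate: [lo_v, hi_v]})
    include = []
    if level.startswith("tissue:"):
        tissue = level.split(":", 1)[1]
        rows[group_name] = tissue
        include = [group_name]
    elif level != "body":
        raise ValueError(f"unknown level {level!r}")
    p = predict_composition(fit_, rows, include_groups=include)
    p_lo, p_hi = p.iloc[0].to_numpy(), p.iloc[1].to_numpy()
    fc = np.where(p_hi >= p_lo, p_hi / p_lo, -(p_lo / p_hi))
    return pd.Series(fc, index=fit_.categories, name="signed_fold_change")
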