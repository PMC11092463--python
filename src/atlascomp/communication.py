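"""Cell-communication strength: filtering, summarising and the beta model.

Communication weights arrive from an upstream ligand-receptor scoring tool
as per-sample values in (0, 1) for sender/receiver cell-type pairs on named
communication axes. Eligibility filtering drops cell types represented by
fewer than ten cells in a sample and then samples left with fewer than two
immune cell types. Age effects on the overall per-cell-type strength are
fitted per tissue with a multilevel beta regression: the logit of the mean
weight is linear in scaled age with dataset-level random intercepts, and
the precision is constant per model (no variability regression is used for
this analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

from . import inference
from .compositional import expit


@dataclass
class CommunicationFilter:
    min_cells_per_type: int = 10
    min_types_per_sample: int = 2


def filter_communication(
    cell_counts: pd.DataFrame,
    thresholds: CommunicationFilter | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Eligible (sample, cell type) pairs from per-sample cell-type counts.

    ``cell_counts`` is long-form with columns sample_id, cell_type, n_cells.
    Cell types with fewer than ten cells are dropped per sample, then
    samples with fewer than two remaining cell types are dropped entirely
    (boundary semantics: exactly ten cells / two types are kept). Returns
    the eligible pairs and an attrition log.
    """
    th = thresholds or CommunicationFilter()
    required = {"sample_id", "cell_type", "n_cells"}
    if not required <= set(cell_counts.columns):
        raise KeyError(f"cell_counts needs columns {sorted(required)}")
    start_pairs = len(cell_counts)
    start_samples = cell_counts["sample_id"].nunique()
    kept = cell_counts[cell_counts["n_cells"] >= th.min_cells_per_type]
    dropped_types = start_pairs - len(kept)
    types_per_sample = kept.groupby("sample_id")["cell_type"].nunique()
    ok = types_per_sample[types_per_sample >= th.min_types_per_sample].index
    out = kept[kept["sample_id"].isin(ok)].reset_index(drop=True)
    attrition = pd.DataFrame([
        {"rule": f"cell_type_min_{th.min_cells_per_type}_cells",
         "pairs_excluded": dropped_types,
         "samples_excluded": 0},
        {"rule": f"sample_min_{th.min_types_per_sample}_cell_types",
         "pairs_excluded": int(len(kept) - len(out)),
         "samples_excluded": int(start_samples - out["sample_id"].nunique())},
    ])
    return out, attrition


def summarise_strength(records: pd.DataFrame) -> pd.DataFrame:
    """Overall outgoing strength per (sample, sender cell type, axis).

    The overall strength of a cell type is the mean of its pairwise weights
    to every other eligible cell type on that axis.
    """
    pair = records[records["receiver"] != "all"]
    pair = pair[pair["receiver"] != pair["sender"]]
    if pair.empty:
        raise ValueError("no eligible sender/receiver pairs to summarise")
    keys = ["sample_id", "sender", "axis"]
    carried = [c for c in ("tissue", "dataset_id", "age_days", "age_scaled")
               if c in pair.columns]
    agg = pair.groupby(keys, as_index=False).agg(
        weight=("weight", "mean"), **{c: (c, "first") for c in carried})
    return agg


# ---------------------------------------------------------------------------
# multilevel beta regression of strength on age
# ---------------------------------------------------------------------------

@dataclass
class WeightModelOptions:
    draws: int = 1000
    chains: int = 4
    seed: int = 0
    min_samples: int = 10
    ci_level: float = 0.95
    prior_sd: float = 2.0
    # lognormal prior on the dataset-intercept sd: with few datasets per
    # tissue a prior with positive density at zero lets the MAP collapse
    # into the hierarchical funnel spike
    log_sigma_prior: tuple[float, float] = (float(np.log(0.3)), 0.7)
    log_kappa_prior: tuple[float, float] = (3.0, 2.0)


class _BetaWeightPosterior:
    """logit(mu) = alpha + beta_age * age + b_dataset;  w ~ Beta(mu k, (1-mu)k).

    Parameters: [alpha, beta_age, b_1..b_D, log_sigma_d, log_kappa].
    """

    def __init__(self, w: np.ndarray, age: np.ndarray, dataset_idx: np.ndarray,
                 n_datasets: int, opts: WeightModelOptions):
        eps = 1e-6
        clipped = np.clip(w, eps, 1 - eps)
        self.n_clipped = int(np.sum(clipped != w))
        self.w = clipped
        self.age = age
        self.idx = dataset_idx
        self.D = n_datasets
        self.opts = opts
        self.size = 2 + n_datasets + 2

    def initial_point(self) -> np.ndarray:
        x = np.zeros(self.size)
        x[-2] = np.log(0.3)
        x[-1] = self.opts.log_kappa_prior[0]
        return x

    def neg_log_posterior(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        opts = self.opts
        alpha, beta = x[0], x[1]
        b = x[2:2 + self.D]
        lam, log_k = x[-2], x[-1]
        if abs(lam) > 8 or not -8 < log_k < 12 or np.any(np.abs(x[:2 + self.D]) > 30):
            return np.inf, np.zeros_like(x)
        sig = np.exp(lam)
        kappa = np.exp(log_k)
        eta = alpha + beta * self.age + b[self.idx]
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        a_, b_ = mu * kappa, (1 - mu) * kappa
        lw, l1w = np.log(self.w), np.log1p(-self.w)
        ll = float(np.sum(gammaln(kappa) - gammaln(a_) - gammaln(b_)
                          + (a_ - 1) * lw + (b_ - 1) * l1w))
        dmu = kappa * (lw - l1w - digamma(a_) + digamma(b_))
        dkappa_each = (digamma(kappa) - mu * digamma(a_)
                       - (1 - mu) * digamma(b_) + mu * lw + (1 - mu) * l1w)
        deta = dmu * mu * (1 - mu)
        grad = np.zeros_like(x)
        grad[0] = deta.sum()
        grad[1] = float((deta * self.age).sum())
        np.add.at(grad, 2 + self.idx, deta)
        grad[-1] = float(dkappa_each.sum()) * kappa

        # priors
        lp = ll
        lp += -0.5 * (alpha ** 2 + beta ** 2) / opts.prior_sd ** 2
        grad[0] += -alpha / opts.prior_sd ** 2
        grad[1] += -beta / opts.prior_sd ** 2
        lp += float(-0.5 * (b ** 2).sum() / sig ** 2 - self.D * lam)
        grad[2:2 + self.D] += -b / sig ** 2
        m_s, s_s = opts.log_sigma_prior
        lp += -0.5 * (lam - m_s) ** 2 / s_s ** 2
        grad[-2] = float((b ** 2).sum() / sig ** 2 - self.D
                         - (lam - m_s) / s_s ** 2)
        m_k, s_k = opts.log_kappa_prior
        lp += -0.5 * (log_k - m_k) ** 2 / s_k ** 2
        grad[-1] += -(log_k - m_k) / s_k ** 2
        if not np.isfinite(lp):
            return np.inf, np.zeros_like(x)
        return -lp, -grad


def fit_weight_model(
    records: pd.DataFrame,
    options: WeightModelOptions | None = None,
    pooled: bool = False,
) -> pd.DataFrame:
    """Posterior age effects on communication strength per (tissue, cell
    type, axis).

    ``records`` holds overall strengths (from :func:`summarise_strength`)
    with columns sample_id, tissue, dataset_id, sender, axis, weight and
    age_scaled. Models are fitted per tissue (``pooled=True`` instead fits
    one model per (cell type, axis) across tissues with tissue treated as an
    extra grouping via the dataset intercepts). An effect is flagged when
    its credible interval excludes zero.
    """
    opts = options or WeightModelOptions()
    group_cols = ["sender", "axis"] if pooled else ["tissue", "sender", "axis"]
    rows = []
    alpha = (1 - opts.ci_level) / 2
    for keys, sub in records.groupby(group_cols):
        if sub["sample_id"].nunique() < opts.min_samples:
            raise ValueError(
                f"fewer than {opts.min_samples} samples for {keys}; "
                "raise min_samples or filter upstream")
        datasets = sorted(sub["dataset_id"].astype(str).unique())
        idx = sub["dataset_id"].astype(str).map(
            {d: i for i, d in enumerate(datasets)}).to_numpy()
        post = _BetaWeightPosterior(
            sub["weight"].to_numpy(float), sub["age_scaled"].to_numpy(float),
            idx, len(datasets), opts)
        rng = np.random.default_rng(opts.seed)
        res = inference.laplace(post.neg_log_posterior, post.initial_point(),
                                n_draws=opts.draws, rng=rng,
                                n_chains=opts.chains)
        beta_draws = res.flat_draws[:, 1]
        lo, hi = np.quantile(beta_draws, [alpha, 1 - alpha])
        key_dict = dict(zip(group_cols, keys if isinstance(keys, tuple) else (keys,)))
        rows.append({
            **key_dict,
            "n_samples": int(sub["sample_id"].nunique()),
            "beta_age_mean": float(beta_draws.mean()),
            "ci_lower": float(lo),
            "ci_upper": float(hi),
            "flagged": bool(lo > 0 or hi < 0),
            "n_weights_clipped": post.n_clipped,
        })
    return pd.DataFrame(rows)
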