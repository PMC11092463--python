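"""Model-based adjusted compositions and ageing trajectories.

Removal of unwanted variation works on the link scale: residuals are the
difference between the centred log-ratio of the observed proportions (with a
0.5 pseudo-count) and the posterior-mean full-model linear predictor; the
target model's predictor plus those residuals, pushed through softmax, gives
adjusted proportions that keep compositional closure. The deterministic
posterior-mean predictor is used rather than posterior-predictive draws so
no extra sampling noise enters the adjusted data (a draw-based mode exists).

Ageing trajectories predict the tissue-level composition on an age grid of
10 to 90 years in steps of 10, move the predictions to the logit scale, and
run a centred, unscaled PCA across the tissue-by-age grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .compositional import clr, logit, proportions_with_pseudocount, softmax
from .containers import CompositionMatrix
from .multilevel import ModelFit, posterior_eta, predict_composition, \
    _default_tissue_group

DEFAULT_AGE_GRID_YEARS = tuple(range(10, 91, 10))


def _mean_eta(fit_: ModelFit, fixed_terms: list[str] | None,
              groups: list[str] | None) -> np.ndarray:
    """Posterior-mean linear predictor restricted to the requested terms."""
    d = fit_.design
    beta_mean = fit_.beta.mean(axis=0)          # (P, K)
    if fixed_terms is None:
        cols = list(range(len(d.x_names)))
    else:
        cols = []
        for term in fixed_terms:
            if term in d.term_columns:
                cols.extend(d.term_columns[term])
            elif term in d.x_names:
                cols.append(d.x_names.index(term))
            else:
                raise KeyError(f"target term {term!r} not in fitted design")
    eta = d.X[:, cols] @ beta_mean[cols]
    for name in (groups if groups is not None else list(d.groups)):
        if name not in d.groups:
            raise KeyError(f"target grouping {name!r} not in fitted design")
        g = d.groups[name]
        U = fit_.u[name].mean(axis=0)           # (L, T, K)
        eta += np.einsum("nt,ntk->nk", g.slopes, U[g.index])
    return eta


def remove_unwanted_variation(
    fit_: ModelFit,
    counts: CompositionMatrix,
    target_fixed: list[str] | None = None,
    target_groups: list[str] | None = (),
) -> pd.DataFrame:
    """Adjusted proportions keeping only the targeted effects.

    ``target_fixed`` lists the fixed terms of interest (None keeps all) and
    ``target_groups`` the random terms of interest (None keeps all, the
    default empty tuple keeps none — dataset/batch structure is then
    removed). With everything targeted the adjusted proportions equal the
    observed pseudo-counted proportions.
    """
    obs = proportions_with_pseudocount(counts.counts.to_numpy(), 0.5)
    eta_full = _mean_eta(fit_, None, None)
    residual = clr(obs, axis=1) - eta_full
    eta_target = _mean_eta(
        fit_, target_fixed,
        None if target_groups is None else list(target_groups))
    adjusted = softmax(eta_target + residual, axis=1)
    return pd.DataFrame(adjusted, index=counts.counts.index,
                        columns=counts.counts.columns)


@dataclass
class TrajectoryResult:
    grid: pd.DataFrame            # tissue, age_years, predicted proportions
    coordinates: pd.DataFrame     # PC coordinates per grid row
    loadings: pd.DataFrame        # category x component
    variance_explained: np.ndarray

    def top_loadings(self, component: int = 0, n: int = 10) -> pd.Series:
        col = self.loadings.iloc[:, component]
        return col.reindex(col.abs().sort_values(ascending=False).index[:n])


def ageing_trajectories(
    fit_: ModelFit,
    tissues: list[str] | None = None,
    age_grid_years: tuple[int, ...] = DEFAULT_AGE_GRID_YEARS,
    age_mean_days: float | None = None,
    age_sd_days: float | None = None,
    group_name: str | None = None,
    n_components: int | None = None,
) -> TrajectoryResult:
    """Tissue-level compositional ageing trajectories in PCA space.

    Ages (years) are converted to the model's scaled-age covariate using the
    cohort's age standardisation (taken from the design metadata unless given
    explicitly). Predictions include the tissue group-level effects; the
    logit-transformed proportions (clipped at 1e-6) are decomposed with a
    centred, unscaled PCA.
    """
    group_name = group_name or _default_tissue_group(fit_)
    g = fit_.design.groups.get(group_name)
    if g is None:
        raise KeyError("fit has no tissue-level grouping")
    if "age_scaled" not in g.term_names:
        raise KeyError("fit has no tissue-level age slopes")
    tissues = list(tissues) if tissues is not None else list(g.levels)
    unknown = set(tissues) - set(g.levels)
    if unknown:
        raise KeyError(f"tissue(s) without fitted group-level effect: "
                       f"{sorted(unknown)}")
    meta = fit_.design.metadata
    age_mean_days = age_mean_days if age_mean_days is not None \
        else meta.get("age_mean_days")
    age_sd_days = age_sd_days if age_sd_days is not None \
        else meta.get("age_sd_days")
    if age_mean_days is None or age_sd_days is None:
        raise ValueError("age standardisation (age_mean_days / age_sd_days) "
                         "unknown; pass it explicitly")

    rows = pd.DataFrame(
        [(t, a) for t in tissues for a in age_grid_years],
        columns=[group_name, "age_years"],
    )
    rows["age_scaled"] = (rows["age_years"] * 365.0 - age_mean_days) / age_sd_days
    pred = predict_composition(fit_, rows, include_groups=[group_name])
    logits = logit(pred.to_numpy(), eps=1e-6)

    n_comp = n_components or min(logits.shape[0], logits.shape[1])
    pca = PCA(n_components=n_comp)              # centres, does not scale
    coords = pca.fit_transform(logits)
    comp_names = [f"PC{i+1}" for i in range(coords.shape[1])]
    grid = pd.concat(
        [rows[[group_name, "age_years"]].rename(columns={group_name: "tissue"}),
         pred.reset_index(drop=True)], axis=1)
    return TrajectoryResult(
        grid=grid,
        coordinates=pd.DataFrame(coords, columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=fit_.categories,
                              columns=comp_names),
        variance_explained=pca.explained_variance_ratio_,
    )
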