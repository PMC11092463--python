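"""Remove unwanted variation and chart compositional ageing trajectories.

Refits the cohort model (same seed as 03), produces dataset/batch-adjusted
proportions keeping only the intercept and age effects, then predicts the
tissue-level composition on the 10-90 year grid (step 10), moves it to the
logit scale and runs the centred, unscaled PCA.

Writes results/analysis/adjusted/{adjusted_proportions.tsv,
trajectory_grid.tsv,trajectory_coordinates.tsv,trajectory_loadings.tsv}.
"""

from pathlib import Path

import pandas as pd

from atlascomp import adjusted_views as av
from atlascomp import multilevel as ml
from atlascomp.containers import CompositionMatrix
from atlascomp.design import DesignSpec, build_design

COHORT = Path("results/analysis/cohort")
OUT = Path("results/analysis/adjusted")
SEED = 20240


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = CompositionMatrix.from_tsv(COHORT / "counts.tsv")
    table = pd.read_csv(COHORT / "design_table.csv")
    table.attrs["age_mean_days"] = float(table["age_days"].mean())
    table.attrs["age_sd_days"] = float(table["age_days"].std(ddof=0))
    design = build_design(table, DesignSpec())
    fit = ml.fit(counts, design, options=ml.FitOptions(seed=SEED, draws=500))

    adjusted = av.remove_unwanted_variation(
        fit, counts, target_fixed=["intercept", "age_scaled"],
        target_groups=())
    adjusted.to_csv(OUT / "adjusted_proportions.tsv", sep="\t",
                    index_label="sample_id")
    print(f"adjusted proportions for {len(adjusted)} samples "
          "(dataset and tissue variation removed, age preserved)")

    traj = av.ageing_trajectories(fit)
    traj.grid.to_csv(OUT / "trajectory_grid.tsv", sep="\t", index=False)
    traj.coordinates.to_csv(OUT / "trajectory_coordinates.tsv", sep="\t",
                            index=False)
    traj.loadings.to_csv(OUT / "trajectory_loadings.tsv", sep="\t",
                         index_label="category")
    ve = traj.variance_explained
    print(f"trajectory grid: {len(traj.grid)} rows "
          f"({traj.grid['tissue'].nunique()} tissues x 9 ages)")
    print(f"variance explained: PC1 {100 * ve[0]:.1f}%, "
          f"PC2 {100 * ve[1]:.1f}%")
    print("top loadings on PC1:")
    print(traj.top_loadings(0, n=4).round(3).to_string())


if __name__ == "__main__":
    main()
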