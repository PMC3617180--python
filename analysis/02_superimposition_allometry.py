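"""Superimpose the specimens and test for evolutionary allometry.

GPA-aligns all configurations, averages to taxon means, regresses taxon
mean shape on centroid size (permutation test of the percent of shape
variation predicted by size), and runs the slope/intercept ANCOVA between
two tree-defined clades. Tables go to results/allometry/.
"""

from pathlib import Path

import pandas as pd

import sciurmorph as sm
from sciurmorph.allometry import test_common_allometry
from sciurmorph.pipeline import default_clades

ROOT = Path(__file__).resolve().parent.parent
BUNDLE = ROOT / "scratch" / "bundle"
OUT = ROOT / "results" / "allometry"


def load_means():
    ds = sm.read_groups(BUNDLE / "groups.tsv", sm.read_tps(BUNDLE / "landmarks.tps"))
    aligned = sm.gpa_align(ds)
    return ds, aligned, sm.taxon_mean_shapes(aligned)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ds, aligned, means = load_means()
    model = sm.fit_allometry(means, n_perm=999, seed=1)
    print(f"shape ~ centroid size across {model.n} taxon means:")
    print(f"  {model.percent_predicted:.2f}% of shape variation predicted by size")
    print(f"  Goodall-style F(1,{model.n - 2}) = {model.goodall_F:.2f}, "
          f"permutation p = {model.p_permutation:.4g}")

    coef = pd.DataFrame(
        {"intercept": model.intercept_shape, "slope": model.slope_vector}
    )
    coef.to_csv(OUT / "regression_coefficients.csv", index_label="coordinate")

    tree = sm.read_tree(BUNDLE / "tree.nwk", means.taxa)
    clades = default_clades(tree)
    grouping = {t: name for name, members in clades.items() for t in members}
    rep = test_common_allometry(means, grouping, n_perm=199, seed=2)
    print(f"clade ANCOVA ({' vs '.join(rep.groups)}):")
    print(f"  slope heterogeneity F{rep.slope_df} = {rep.slope_F:.2f}, "
          f"p = {rep.slope_p:.3f} (permutation {rep.slope_p_perm:.3f})")
    print(f"  intercepts          F{rep.intercept_df} = {rep.intercept_F:.2f}, "
          f"p = {rep.intercept_p:.3f} (permutation {rep.intercept_p_perm:.3f})")
    pd.DataFrame(
        {
            "test": ["slope", "intercept"],
            "F": [rep.slope_F, rep.intercept_F],
            "p_parametric": [rep.slope_p, rep.intercept_p],
            "p_permutation": [rep.slope_p_perm, rep.intercept_p_perm],
        }
    ).to_csv(OUT / "ancova.csv", index=False)


if __name__ == "__main__":
    main()
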