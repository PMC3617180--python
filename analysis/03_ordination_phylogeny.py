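"""Size-corrected shape ordination and the phylogeny mapped onto it.

PCA of the residual (size-corrected) taxon-mean covariance; squared-change
parsimony reconstruction of ancestral shapes; permutation test of
phylogenetic signal for the whole tree and for two clades; exact SCI/SRI
homoplasy indices for the small clade. Tables to results/phylogeny/.
"""

import importlib.util
import sys
from pathlib import Path

import pandas as pd

import sciurmorph as sm
from sciurmorph.pipeline import default_clades

ROOT = Path(__file__).resolve().parent.parent
BUNDLE = ROOT / "scratch" / "bundle"
OUT = ROOT / "results" / "phylogeny"

spec = importlib.util.spec_from_file_location(
    "step02", Path(__file__).parent / "02_superimposition_allometry.py"
)
step02 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(step02)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    _, aligned, means = step02.load_means()
    model = sm.fit_allometry(means, n_perm=199, seed=1)
    residuals = sm.residual_shapes(model, means)
    pca = sm.fit_pca(residuals, basis="size_corrected")
    shares = ", ".join(f"PC{i + 1} {v:.2f}%" for i, v in
                       enumerate(pca.percent_variance[:4]))
    print(f"size-corrected PCA of {means.n} taxon means: {shares}")
    pd.DataFrame(
        pca.scores, index=pca.taxa,
        columns=[f"PC{i + 1}" for i in range(pca.n_axes)],
    ).to_csv(OUT / "pca_scores.csv")

    tree = sm.read_tree(BUNDLE / "tree.nwk", means.taxa)
    tips = {t: residuals.tangent_coords[i] for i, t in enumerate(residuals.taxa)}
    anc = sm.reconstruct_ancestral_shapes(tree, tips)
    node_scores, edges = sm.map_tree_to_ordination(pca, tree, anc)
    node_scores.to_csv(OUT / "tree_projection.csv")
    pd.DataFrame(edges, columns=["from", "to"]).to_csv(
        OUT / "tree_edges.csv", index=False
    )

    sig = sm.permutation_signal_test(tree, tips, n_perm=999, seed=3)
    print(f"whole tree: length = {sig.observed_length:.4f}, "
          f"p (no signal) = {sig.p_value:.4g}")

    rows = [("full_tree", tree.n_tips, sig.observed_length, sig.p_value,
             None, None)]
    for name, members in default_clades(tree).items():
        sub = tree.extract_clade(members)
        sub_tips = {t: tips[t] for t in members}
        s = sm.permutation_signal_test(sub, sub_tips, n_perm=999, seed=4)
        sci = sri = None
        if sub.n_tips <= 8:
            h = sm.homoplasy_indices(sub, sub_tips, max_taxa_exhaustive=8)
            sci, sri = h.sci, h.sri
            print(f"{name} ({sub.n_tips} tips): length = {s.observed_length:.4f}, "
                  f"p = {s.p_value:.4g}, SCI = {sci:.3f}, SRI = {sri:.3f}")
        else:
            print(f"{name} ({sub.n_tips} tips): length = {s.observed_length:.4f}, "
                  f"p = {s.p_value:.4g} (too many taxa for exact Steiner search)")
        rows.append((name, sub.n_tips, s.observed_length, s.p_value, sci, sri))
    pd.DataFrame(
        rows, columns=["scope", "n_tips", "tree_length", "p_value", "SCI", "SRI"]
    ).to_csv(OUT / "signal_tests.csv", index=False)


if __name__ == "__main__":
    main()
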