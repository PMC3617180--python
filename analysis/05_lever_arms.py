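"""Mechanical advantage of the jaw muscles across shapes.

Computes moment arms / incisor resistance arm ratios for every taxon mean,
for dietary group means, for shapes reconstructed along PC1/PC2 of the
size-corrected ordination, and for allometry-predicted shapes at small and
large centroid sizes. Tables to results/biomechanics/.
"""

import importlib.util
from pathlib import Path

import numpy as np

import sciurmorph as sm
from sciurmorph.datatypes import vector_to_shape

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "biomechanics"

spec = importlib.util.spec_from_file_location(
    "step02", Path(__file__).parent / "02_superimposition_allometry.py"
)
step02 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(step02)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ds, aligned, means = step02.load_means()

    taxon_shapes = {
        t: vector_to_shape(means.tangent_coords[i])
        for i, t in enumerate(means.taxa)
    }
    taxa_table = sm.advantage_table(taxon_shapes, decimals=2)
    taxa_table.to_csv(OUT / "taxon_means.csv")

    named = {}
    Y = aligned.tangent_coords
    diets = np.array(ds.diets)
    for grp in sorted(set(diets) - {"ungrouped"}):
        named[f"{grp} mean"] = vector_to_shape(Y[diets == grp].mean(axis=0))

    model = sm.fit_allometry(means, n_perm=99, seed=1)
    for cs in (100.0, 800.0):
        named[f"centroid size = {cs:.0f} mm"] = model.predict(cs)

    residuals = sm.residual_shapes(model, means)
    pca = sm.fit_pca(residuals, basis="size_corrected")
    for s in (-0.20, 0.15):
        named[f"PC1 score = {s:+.2f}"] = sm.shape_at_score(pca, 1, s)
    for s in (-0.15, 0.15):
        named[f"PC2 score = {s:+.2f}"] = sm.shape_at_score(pca, 2, s)

    recon = sm.advantage_table(named, decimals=2)
    recon.to_csv(OUT / "reconstructed_shapes.csv")
    print("mechanical advantage (moment arm / incisor resistance arm):")
    print(recon.to_string())


if __name__ == "__main__":
    main()
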