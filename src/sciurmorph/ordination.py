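"""Principal component analysis of shape covariance and tree projection.

The PCA eigendecomposes the covariance matrix of tangent coordinates across
taxon means (raw, or size-corrected residuals). Because four dimensions are
lost to the superimposition (two to translation, one each to scale and
rotation), at most min(n-1, 2k-4) axes are non-null. Reconstructed shapes
along an axis (center + score x eigenvector) provide the wireframes drawn
along ordination axes; squared-change-parsimony node shapes projected onto
the axes place the phylogeny inside the ordination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ShapeDataset, vector_to_shape
from .io import PhylogeneticTree
from .phylo import AncestralStates


@dataclass
class ShapePCA:
    eigenvalues: np.ndarray  # (m,), descending, non-null only
    eigenvectors: np.ndarray  # (m, 2k), rows orthonormal
    scores: np.ndarray  # (n, m)
    percent_variance: np.ndarray  # (m,), sums to 100
    center: np.ndarray  # (2k,) mean shape of the ordination
    taxa: list[str]
    basis: str  # "raw" or "size_corrected"

    @property
    def n_axes(self) -> int:
        return self.eigenvalues.size

    def project(self, shape_vec: np.ndarray) -> np.ndarray:
        """Scores of an arbitrary 2k shape vector (or k x 2 shape) on all axes."""
        v = np.asarray(shape_vec, dtype=float).reshape(-1)
        return (v - self.center) @ self.eigenvectors.T


NULL_AXIS_RTOL = 1e-12


def fit_pca(dataset: ShapeDataset, basis: str = "raw") -> ShapePCA:
    """PCA of the covariance matrix of tangent coordinates (taxon means as rows).

    Null axes (eigenvalue below 1e-12 x trace) are dropped; each retained
    eigenvector's largest-magnitude entry is made positive so output is
    deterministic across platforms.
    """
    Y = dataset.require_aligned()
    if dataset.n < 3:
        raise ValueError("PCA needs at least 3 taxa")
    center = Y.mean(axis=0)
    Yc = Y - center
    cov = (Yc.T @ Yc) / (dataset.n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order].T  # rows
    trace = float(np.sum(np.clip(evals, 0, None)))
    keep = evals > NULL_AXIS_RTOL * trace
    evals, evecs = evals[keep], evecs[keep]
    # deterministic sign convention
    for i in range(evecs.shape[0]):
        j = np.argmax(np.abs(evecs[i]))
        if evecs[i, j] < 0:
            evecs[i] = -evecs[i]
    scores = Yc @ evecs.T
    percent = 100.0 * evals / evals.sum()
    return ShapePCA(
        eigenvalues=evals,
        eigenvectors=evecs,
        scores=scores,
        percent_variance=percent,
        center=center,
        taxa=list(dataset.taxa),
        basis=basis,
    )


def shape_at_score(pca: ShapePCA, axis: int, score: float) -> np.ndarray:
    """Reconstructed k x 2 shape at a given score along a PC (1-based axis).

    Score 0 returns the ordination's mean shape; the reconstruction is linear
    in the score.
    """
    if not 1 <= axis <= pca.n_axes:
        raise ValueError(f"axis {axis} out of range 1..{pca.n_axes}")
    vec = pca.center + score * pca.eigenvectors[axis - 1]
    return vector_to_shape(vec)


def map_tree_to_ordination(
    pca: ShapePCA, tree: PhylogeneticTree, ancestors: AncestralStates
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Project tips and reconstructed internal nodes into PC space.

    Returns a node-by-axis score table (index: node label) and the labeled
    edge list for drawing the tree inside the ordination.
    """
    if set(ancestors.tip_index) != set(pca.taxa):
        raise ValueError("ancestral states and PCA cover different taxa")
    scores = (ancestors.states - pca.center) @ pca.eigenvectors.T
    table = pd.DataFrame(
        scores,
        index=ancestors.node_labels,
        columns=[f"PC{i + 1}" for i in range(pca.n_axes)],
    )
    return table, ancestors.labeled_edges()
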