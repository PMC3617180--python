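"""Generalized Procrustes Analysis and shape-space geometry.

Conventions follow the full-Procrustes / unit-centroid-size superimposition
standard in geometric-morphometrics software: every configuration is centered,
scaled to unit centroid size, and rotated (reflections disallowed) to the
iteratively re-estimated consensus; tangent coordinates are the orthogonal
projection onto the tangent space at the consensus.
"""

from __future__ import annotations

import warnings
from collections import OrderedDict
from typing import Sequence

import numpy as np

from .datatypes import (
    LandmarkConfiguration,
    ShapeDataset,
    SpecimenRecord,
    centroid_size,
    shapes_to_matrix,
    vector_to_shape,
)

__all__ = [
    "centroid_size",
    "center_scale",
    "optimal_rotation",
    "procrustes_distance",
    "gpa_align",
    "taxon_mean_shapes",
]


def center_scale(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Center a configuration and scale it to unit centroid size.

    Returns the pre-shape and the original centroid size.
    """
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs == 0.0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return centered / cs, cs


def optimal_rotation(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Proper rotation R (det = +1) minimizing ``||Y - X R||`` over SO(2).

    X and Y are k x 2 centered configurations. Reflections are never used:
    a reflection-only match is left as a large residual, because all
    mandibles are digitized in the same buccal orientation.
    """
    H = X.T @ Y
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    if d == 0:
        d = 1.0
    return U @ np.diag([1.0, d]) @ Vt


def _as_config(shape: np.ndarray) -> np.ndarray:
    shape = np.asarray(shape, dtype=float)
    if shape.ndim == 1:
        shape = vector_to_shape(shape)
    return shape


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two configurations.

    Minimum root summed squared difference after centering, scaling both to
    unit centroid size, optimal proper rotation, and the optimal relative
    scaling of one onto the other; symmetric in its arguments. Accepts k x 2
    arrays or flat 2k vectors.
    """
    A = _as_config(a)
    B = _as_config(b)
    if A.shape != B.shape:
        raise ValueError(f"landmark count mismatch: {A.shape} vs {B.shape}")
    X, _ = center_scale(A)
    Y, _ = center_scale(B)
    R = optimal_rotation(X, Y)
    beta = float(np.sum((X @ R) * Y))  # optimal scale; = cos of Procrustes angle
    return float(np.sqrt(max(0.0, 1.0 - beta**2)))


def _rotate_to(X: np.ndarray, ref: np.ndarray) -> np.ndarray:
    return X @ optimal_rotation(X, ref)


def _principal_axis_rotation(shape: np.ndarray) -> np.ndarray:
    """Proper rotation aligning a centered shape to its principal axes.

    The major axis goes to x; the 180-degree ambiguity is resolved by a fixed
    generic linear functional of the rotated coordinates.
    """
    _, _, Vt = np.linalg.svd(shape, full_matrices=False)
    R = Vt.T
    if np.linalg.det(R) < 0:
        R = R @ np.diag([1.0, -1.0])
    rotated = shape @ R
    weights = np.arange(1, shape.shape[0] + 1, dtype=float)
    if weights @ rotated[:, 0] + 0.1 * (weights**2) @ rotated[:, 1] < 0:
        R = -R  # 180-degree turn (still proper)
    return R


def gpa_align(
    dataset: ShapeDataset,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ShapeDataset:
    """Generalized Procrustes alignment of a dataset.

    Each configuration is centered and scaled to unit centroid size, then
    rotated to the consensus; the consensus is the arithmetic mean of the
    rotated configurations, re-scaled to unit centroid size each iteration.
    The first specimen seeds the initial reference. Iteration stops when the
    consensus moves by less than ``tol`` in Procrustes distance, or after
    ``max_iter`` iterations (then a warning is issued and the result flagged
    via ``gpa_converged=False``).

    Tangent coordinates are obtained by orthogonal projection at the
    consensus and stored as full coordinates near the consensus (so that
    averaging tangent rows yields meaningful shapes).
    """
    if dataset.n < 2:
        raise ValueError("GPA needs at least 2 specimens")
    pre = [center_scale(s.configuration.coords)[0] for s in dataset.specimens]
    ref = pre[0]
    aligned = [_rotate_to(X, ref) for X in pre]
    mean = np.mean(aligned, axis=0)
    mean /= np.sqrt(np.sum(mean**2))
    converged = False
    for _ in range(max_iter):
        aligned = [_rotate_to(X, mean) for X in pre]
        new_mean = np.mean(aligned, axis=0)
        new_mean /= np.sqrt(np.sum(new_mean**2))
        shift = procrustes_distance(new_mean, mean)
        mean = new_mean
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations", RuntimeWarning
        )
    # final rotation pass against the converged consensus
    aligned = [_rotate_to(X, mean) for X in pre]

    # standardize orientation (principal axes of the consensus, deterministic
    # sign) so the output is invariant -- not merely equivariant -- under a
    # common rigid motion of all inputs
    R_std = _principal_axis_rotation(mean)
    mean = mean @ R_std
    aligned = [X @ R_std for X in aligned]

    c = mean.reshape(-1)
    rows = shapes_to_matrix(aligned)
    # orthogonal tangent projection at the consensus, re-expressed about it
    proj = rows - np.outer(rows @ c, c)
    tangent = proj + c

    return ShapeDataset(
        specimens=list(dataset.specimens),
        consensus=mean,
        tangent_coords=tangent,
        gpa_converged=converged,
        mean_centroid_sizes=None,
    )


def taxon_mean_shapes(dataset: ShapeDataset) -> ShapeDataset:
    """Average tangent coordinates (and centroid sizes) within each taxon.

    Returns a new aligned dataset with one record per taxon, in order of
    first appearance. Diet/locomotion labels are carried over when they are
    unanimous within the taxon, otherwise set to ``ungrouped``.
    """
    coords = dataset.require_aligned()
    groups: "OrderedDict[str, list[int]]" = OrderedDict()
    for i, taxon in enumerate(dataset.taxa):
        groups.setdefault(taxon, []).append(i)

    cs = np.array([s.centroid_size for s in dataset.specimens])
    records = []
    tangent_rows = []
    mean_cs = []
    for taxon, idx in groups.items():
        mean_vec = coords[idx].mean(axis=0)
        diets = {dataset.specimens[i].diet for i in idx}
        locos = {dataset.specimens[i].locomotion for i in idx}
        records.append(
            SpecimenRecord(
                configuration=LandmarkConfiguration(taxon, vector_to_shape(mean_vec)),
                taxon=taxon,
                diet=diets.pop() if len(diets) == 1 else "ungrouped",
                locomotion=locos.pop() if len(locos) == 1 else "ungrouped",
            )
        )
        tangent_rows.append(mean_vec)
        mean_cs.append(cs[idx].mean())

    return ShapeDataset(
        specimens=records,
        consensus=dataset.consensus,
        tangent_coords=np.stack(tangent_rows),
        gpa_converged=dataset.gpa_converged,
        mean_centroid_sizes=np.array(mean_cs),
    )
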