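"""Shared fixtures: small synthetic shape datasets built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from sciurmorph import (
    LandmarkConfiguration,
    ShapeDataset,
    SpecimenRecord,
    gpa_align,
    make_template,
)


def rotation(theta: float) -> np.ndarray:
    return np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )


def dataset_from_shapes(shapes, taxa=None, diets=None, ids=None) -> ShapeDataset:
    """Build an (unaligned) dataset from a list of k x 2 arrays."""
    n = len(shapes)
    taxa = taxa or [f"t{i}" for i in range(n)]
    diets = diets or ["ungrouped"] * n
    ids = ids or [f"s{i}" for i in range(n)]
    specs = [
        SpecimenRecord(LandmarkConfiguration(ids[i], shapes[i]), taxon=taxa[i],
                       diet=diets[i])
        for i in range(n)
    ]
    return ShapeDataset(specimens=specs)


def tangent_dataset(rows, consensus, taxa=None, diets=None, cs=None) -> ShapeDataset:
    """Build an already-aligned dataset directly from tangent rows.

    Used by statistical tests that exercise post-GPA machinery on exactly
    controlled coordinates.
    """
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[0]
    ds = dataset_from_shapes(
        [rows[i].reshape(-1, 2) for i in range(n)], taxa=taxa, diets=diets
    )
    ds.consensus = np.asarray(consensus, dtype=float).reshape(-1, 2)
    ds.tangent_coords = rows
    if cs is not None:
        ds.mean_centroid_sizes = np.asarray(cs, dtype=float)
    return ds


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def mandible():
    return make_template("squirrel_mandible_14")


@pytest.fixture
def aligned_scatter(rng, mandible):
    """Nine specimens in three taxa: template + small noise, GPA-aligned."""
    shapes = []
    taxa = []
    for t in range(3):
        for i in range(3):
            noise = rng.normal(0, 0.2, mandible.shape)
            shapes.append(mandible + noise)
            taxa.append(f"taxon{t}")
    ds = dataset_from_shapes(shapes, taxa=taxa)
    return gpa_align(ds)
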