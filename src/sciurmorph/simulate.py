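"""Synthetic landmark datasets with the structure the analyses assume.

The generator emulates the data model behind a clade-wide mandible study:
per-taxon mean shapes evolve by Brownian motion on a (Yule or user-supplied)
phylogeny; additive dietary-group effects shift group members along fixed
shape vectors; a common allometric vector scales with centroid size; and
individual specimens scatter isotropically around their taxon mean. All
shape effects are kept small relative to centroid size, so the simulated
data live in the small-variation regime where tangent-space linear methods
are valid. Ground truth (taxon means, ancestral node shapes, the allometric
vector, group effects and labels) is recorded for recovery tests.

Defaults mirror a realistic study design for this system: 44 genera, about
seven specimens each (roughly 300 mandibles), seven dietary and three
locomotor categories, centroid sizes spanning pygmy squirrels to marmots
(50-800 mm), and one taxon of unknown ecology left ungrouped the way a
fossil is.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .datatypes import (
    DIET_GROUPS,
    LOCOMOTION_GROUPS,
    LandmarkConfiguration,
    ShapeDataset,
    SpecimenRecord,
)
from .io import PhylogeneticTree, write_tps

#: 14-landmark mandible template (mm, buccal view: x anterior, y dorsal).
#: Landmark roles follow the sciurid scheme: 1 antero-dorsal incisive
#: alveolus, 2 diastema, 3 anterior premolar alveolus, 4 coronoid base,
#: 5 coronoid tip, 6 incisura, 7/8 anterior/posterior condyle edges,
#: 9 posterior mandible edge, 10/11 angular process (posterior/ventral),
#: 12 ventral ramus border, 13 antero-ventral incisive alveolus,
#: 14 anterior masseteric ridge. The condyle-incisor distance (resistance
#: arm) exceeds every default muscle moment arm, as in real mandibles.
MANDIBLE_TEMPLATE_14 = np.array(
    [
        [28.0, 8.0],  # 1 incisive alveolus, antero-dorsal
        [22.0, 6.0],  # 2 diastema
        [18.0, 7.0],  # 3 premolar alveolus
        [8.0, 8.0],  # 4 coronoid base
        [6.0, 16.0],  # 5 coronoid tip
        [3.0, 11.0],  # 6 incisura
        [1.0, 12.0],  # 7 condyle, anterior
        [-1.0, 11.0],  # 8 condyle, posterior
        [0.0, 6.0],  # 9 posterior edge
        [-2.0, 2.0],  # 10 angular process, posterior tip
        [2.0, -1.0],  # 11 angular process, ventral
        [10.0, 1.0],  # 12 ventral ramus border
        [27.0, 5.0],  # 13 incisive alveolus, antero-ventral
        [16.0, 3.0],  # 14 masseteric ridge
    ]
)


def make_template(style: str = "squirrel_mandible_14", k: int = 4) -> np.ndarray:
    """A fixed, documented k x 2 template configuration.

    ``squirrel_mandible_14`` is the 14-landmark mandible above; ``polygon``
    is a regular k-gon placed so that ``polygon(4)`` is the unit square.
    """
    if style == "squirrel_mandible_14":
        return MANDIBLE_TEMPLATE_14.copy()
    if style == "polygon":
        if k < 3:
            raise ValueError("polygon needs k >= 3")
        angles = np.deg2rad(225.0 + 360.0 * np.arange(k) / k)
        r = np.sqrt(2.0) / 2.0
        return 0.5 + r * np.column_stack([np.cos(angles), np.sin(angles)])
    raise ValueError(f"unknown template style {style!r}")


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic dataset.

    Shape-effect magnitudes are in Procrustes (unit-centroid-size) units per
    coordinate; centroid sizes in mm.
    """

    seed: int
    style: str = "squirrel_mandible_14"
    k: int = 14
    n_taxa: int = 44
    specimens_per_taxon: int = 7
    newick: Optional[str] = None  # user-supplied topology; Yule when None
    bm_sd: float = 0.01  # BM step SD per coordinate per unit branch
    diet_effect: float = 0.05  # norm of each dietary-group shape offset
    allometry_effect: float = 0.2  # total shape shift across the CS range
    cs_range: tuple[float, float] = (50.0, 800.0)  # log-uniform CS draw (mm)
    specimen_cs_cv: float = 0.03  # lognormal spread of specimen CS about taxon CS
    noise_sd: float = 0.01  # per-coordinate specimen noise SD
    n_ungrouped_taxa: int = 1  # taxa of unknown ecology (fossil analogs)

    def __post_init__(self) -> None:
        for name in ("bm_sd", "diet_effect", "allometry_effect", "noise_sd",
                     "specimen_cs_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis tries to recover."""

    taxon_means: dict[str, list[float]]  # unit-CS shape vectors (2k)
    node_shapes: dict[str, list[float]]  # BM states at surviving internal nodes
    allometric_vector: list[float]  # true b: d(shape)/d(CS), per mm
    diet_effects: dict[str, list[float]]
    diet_of: dict[str, str]
    locomotion_of: dict[str, str]
    centroid_size_of: dict[str, float]
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def yule_topology(n_taxa: int, rng: np.random.Generator) -> str:
    """Random Yule (pure-birth) topology as a newick string, unit lengths."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    root = {"children": None, "label": None}
    leaves = [root]
    while len(leaves) < n_taxa:
        target = leaves.pop(int(rng.integers(len(leaves))))
        a = {"children": None, "label": None}
        b = {"children": None, "label": None}
        target["children"] = [a, b]
        leaves.extend([a, b])
    counter = [0]

    def serialize(node) -> str:
        if node["children"] is None:
            counter[0] += 1
            return f"taxon_{counter[0]:02d}"
        return "(" + ",".join(serialize(c) for c in node["children"]) + ")"

    return serialize(root) + ";"


def _unit_direction(rng: np.random.Generator, d: int) -> np.ndarray:
    v = rng.standard_normal(d)
    return v / np.linalg.norm(v)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ShapeDataset, PhylogeneticTree, GroundTruth]:
    """Simulate a raw (unaligned, mm-scale) landmark dataset with ground truth.

    Taxon mean shape = template + BM walk along the tree + dietary-group
    offset + allometric vector x (CS - midrange CS); specimens add isotropic
    landmark noise. Raw specimen configurations are randomly rotated,
    translated and scaled to the specimen centroid size, so the dataset
    genuinely exercises the superimposition. Bit-reproducible from
    (config, seed).
    """
    rng = np.random.default_rng(config.seed)
    template = make_template(config.style, config.k)
    k = template.shape[0]
    d = 2 * k
    t0 = template - template.mean(axis=0)
    t0 = (t0 / np.sqrt(np.sum(t0**2))).reshape(-1)  # unit-CS template vector

    newick = config.newick or yule_topology(config.n_taxa, rng)
    tree = PhylogeneticTree.from_newick(newick)
    taxa = tree.tip_labels
    if len(taxa) != config.n_taxa and config.newick is None:
        raise RuntimeError("generated tree tip count mismatch")

    # Brownian motion along the tree (unit branch lengths), root at template
    node_state: dict[int, np.ndarray] = {}
    internal_labels = tree.internal_labels()
    node_shapes: dict[str, list[float]] = {}
    tip_bm: dict[str, np.ndarray] = {}
    for node in tree.dtree.preorder_node_iter():
        if node.parent_node is None:
            state = t0.copy()
        else:
            state = node_state[id(node.parent_node)] + rng.normal(
                0.0, config.bm_sd, d
            )
        node_state[id(node)] = state
        if node.is_leaf():
            tip_bm[node.taxon.label] = state
        elif id(node) in internal_labels:
            node_shapes[internal_labels[id(node)]] = state.tolist()

    # dietary and locomotor assignment: balanced, shuffled
    diet_cats = [g for g in DIET_GROUPS if g != "ungrouped"]
    loco_cats = [g for g in LOCOMOTION_GROUPS if g != "ungrouped"]
    diet_pool = [diet_cats[i % len(diet_cats)] for i in range(len(taxa))]
    loco_pool = [loco_cats[i % len(loco_cats)] for i in range(len(taxa))]
    rng.shuffle(diet_pool)
    rng.shuffle(loco_pool)
    diet_of = dict(zip(taxa, diet_pool))
    loco_of = dict(zip(taxa, loco_pool))
    ungrouped = list(rng.choice(taxa, size=config.n_ungrouped_taxa, replace=False))
    for t in ungrouped:
        diet_of[t] = "ungrouped"
        loco_of[t] = "ungrouped"

    diet_effects = {
        g: config.diet_effect * _unit_direction(rng, d) for g in diet_cats
    }

    # centroid sizes and the allometric vector
    lo, hi = config.cs_range
    cs_of = {
        t: float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) for t in taxa
    }
    cs_mid = float(np.exp((np.log(lo) + np.log(hi)) / 2.0))
    b = (config.allometry_effect / (hi - lo)) * _unit_direction(rng, d)

    taxon_means: dict[str, np.ndarray] = {}
    for t in taxa:
        mean = tip_bm[t].copy()
        if diet_of[t] != "ungrouped":
            mean = mean + diet_effects[diet_of[t]]
        mean = mean + b * (cs_of[t] - cs_mid)
        taxon_means[t] = mean

    specimens = []
    for t in taxa:
        for i in range(config.specimens_per_taxon):
            vec = taxon_means[t] + rng.normal(0.0, config.noise_sd, d)
            shape = vec.reshape(-1, 2)
            shape = shape - shape.mean(axis=0)
            shape = shape / np.sqrt(np.sum(shape**2))
            cs = cs_of[t] * float(np.exp(rng.normal(0.0, config.specimen_cs_cv)))
            theta = rng.uniform(0.0, 2.0 * np.pi)
            R = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            raw = cs * shape @ R.T + rng.uniform(-50.0, 50.0, 2)
            specimens.append(
                SpecimenRecord(
                    configuration=LandmarkConfiguration(f"{t}_sp{i + 1}", raw),
                    taxon=t,
                    diet=diet_of[t],
                    locomotion=loco_of[t],
                )
            )

    dataset = ShapeDataset(specimens=specimens)
    truth = GroundTruth(
        taxon_means={t: v.tolist() for t, v in taxon_means.items()},
        node_shapes=node_shapes,
        allometric_vector=b.tolist(),
        diet_effects={g: v.tolist() for g, v in diet_effects.items()},
        diet_of=diet_of,
        locomotion_of=loco_of,
        centroid_size_of=cs_of,
        config={**asdict(config), "newick": newick},
    )
    return dataset, tree, truth


def write_fixture_bundle(
    config: SimulationConfig, outdir, force: bool = False
) -> Path:
    """Write landmarks.tps, tree.nwk, groups.tsv, truth.json and a config echo.

    Refuses to write into an existing non-empty directory unless ``force``.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()):
        if not force:
            raise FileExistsError(f"{outdir} exists and is not empty (use force=True)")
        shutil.rmtree(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    dataset, tree, truth = simulate_dataset(config)
    write_tps(dataset, outdir / "landmarks.tps")
    (outdir / "tree.nwk").write_text(truth.config["newick"] + "\n")
    with open(outdir / "groups.tsv", "w") as fh:
        fh.write("specimen_id\ttaxon\tdiet\tlocomotion\n")
        for s in dataset.specimens:
            fh.write(f"{s.specimen_id}\t{s.taxon}\t{s.diet}\t{s.locomotion}\n")
    truth.to_json(outdir / "truth.json")
    with open(outdir / "config.txt", "w") as fh:
        for key, value in asdict(config).items():
            fh.write(f"{key} = {value}\n")
    return outdir
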