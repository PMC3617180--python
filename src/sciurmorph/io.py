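"""Readers and writers: TPS landmark files, newick/NEXUS trees, group tables.

The TPS dialect accepted here is the tpsDig family: records start with an
``LM=k`` line followed by k whitespace-separated ``x y`` rows, then optional
``KEY=value`` lines (``ID=``, ``SCALE=``, ``IMAGE=``; unknown keys ignored).
``SCALE`` multiplies the stored coordinates, converting pixels to mm.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import dendropy
import numpy as np
import pandas as pd

from .datatypes import (
    DIET_GROUPS,
    LOCOMOTION_GROUPS,
    DatasetInconsistencyError,
    LandmarkConfiguration,
    ShapeDataset,
    SpecimenRecord,
    VocabularyError,
)

PathLike = Union[str, Path]


class TPSParseError(ValueError):
    """Raised on malformed TPS content; carries the offending line number."""


class TreeReconciliationError(ValueError):
    """Raised when dataset taxa and tree tips cannot be matched one-to-one."""


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------

def read_tps(path: PathLike) -> ShapeDataset:
    """Read a TPS file into a :class:`ShapeDataset` of unlabeled specimens.

    One :class:`SpecimenRecord` per TPS record, order preserved. Coordinates
    are multiplied by ``SCALE`` when present; centroid size is computed from
    the scaled coordinates.
    """
    text = Path(path).read_text()
    records = _parse_tps_text(text)
    if not records:
        raise TPSParseError(f"{path}: no LM= records found")
    specimens = []
    ks = set()
    for i, (sid, coords, scale) in enumerate(records):
        coords = coords * scale
        specimen_id = sid if sid is not None else f"specimen_{i + 1}"
        specimens.append(
            SpecimenRecord(LandmarkConfiguration(specimen_id, coords))
        )
        ks.add(coords.shape[0])
        if len(ks) > 1:
            raise DatasetInconsistencyError(
                f"{path}: record {specimen_id!r} has k={coords.shape[0]}, "
                f"differing from earlier records"
            )
    return ShapeDataset(specimens=specimens)


def _parse_tps_text(text: str) -> list[tuple[Optional[str], np.ndarray, float]]:
    records: list[tuple[Optional[str], np.ndarray, float]] = []
    lines = text.splitlines()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TPSParseError(f"line {i + 1}: expected LM= record header, got {line!r}")
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSParseError(f"line {i + 1}: bad landmark count in {line!r}") from exc
        i += 1
        coords = np.empty((k, 2), dtype=float)
        for j in range(k):
            if i >= n:
                raise TPSParseError(f"line {i + 1}: record truncated, expected {k} rows")
            parts = lines[i].split()
            if len(parts) != 2:
                raise TPSParseError(
                    f"line {i + 1}: expected two coordinates, got {lines[i]!r}"
                )
            try:
                coords[j] = [float(parts[0]), float(parts[1])]
            except ValueError as exc:
                raise TPSParseError(
                    f"line {i + 1}: non-numeric coordinate {lines[i]!r}"
                ) from exc
            i += 1
        sid: Optional[str] = None
        scale = 1.0
        while i < n and "=" in lines[i] and not lines[i].strip().upper().startswith("LM="):
            key, _, value = lines[i].partition("=")
            key = key.strip().upper()
            if key == "ID":
                sid = value.strip()
            elif key == "SCALE":
                try:
                    scale = float(value)
                except ValueError as exc:
                    raise TPSParseError(f"line {i + 1}: bad SCALE value") from exc
            # IMAGE= and unknown KEY=value lines are ignored
            i += 1
        records.append((sid, coords, scale))
    return records


def write_tps(dataset: ShapeDataset, path: PathLike) -> None:
    """Write a dataset to TPS, one record per specimen, deterministic order."""
    buf = _io.StringIO()
    for s in dataset.specimens:
        buf.write(f"LM={s.configuration.k}\n")
        for x, y in s.configuration.coords:
            buf.write(f"{x:.10f} {y:.10f}\n")
        buf.write(f"ID={s.specimen_id}\n")
    Path(path).write_text(buf.getvalue())


def write_shapes_tps(shapes: Mapping[str, np.ndarray], path: PathLike) -> None:
    """Write named k x 2 shapes (e.g. consensus, ancestral states) as TPS."""
    specs = [
        SpecimenRecord(LandmarkConfiguration(name, np.asarray(coords)))
        for name, coords in shapes.items()
    ]
    write_tps(ShapeDataset(specimens=specs), path)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class PhylogeneticTree:
    """A rooted topology over analysis taxa; unit branch lengths by convention.

    Branch lengths are overwritten with 1 at import — the analyses here treat
    the tree as topology only.
    """

    dtree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            raise TreeReconciliationError("duplicate tip labels in tree")
        for edge in self.dtree.preorder_edge_iter():
            edge.length = 1.0

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.dtree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.dtree.leaf_nodes())

    def as_newick(self) -> str:
        return self.dtree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def extract_clade(self, taxa: Sequence[str]) -> "PhylogeneticTree":
        """Restrict the tree to a subset of tips (a user-defined clade)."""
        missing = sorted(set(taxa) - set(self.tip_labels))
        if missing:
            raise TreeReconciliationError(f"taxa not in tree: {missing}")
        sub = self.dtree.extract_tree_with_taxa_labels(labels=list(taxa))
        return PhylogeneticTree(sub)

    def adjacency(
        self, suppress_degree_two: bool = False
    ) -> tuple[dict[str, int], list[tuple[int, int]], int]:
        """Node indexing for the squared-change linear system.

        Returns ``(tip_index, edges, n_nodes)`` where tips get indices
        ``0..n_tips-1`` (order of ``tip_labels``) and internal nodes follow
        in preorder. Edges are undirected index pairs. The tree is used as
        given — a degree-2 root contributes a reconstructed node of its own,
        the convention of rooted squared-change parsimony. Pass
        ``suppress_degree_two=True`` for the unrooted topology (used when
        comparing against the Steiner enumeration, which is over unrooted
        trees).
        """
        tip_index: dict[str, int] = {}
        node_index: dict[int, int] = {}
        next_id = 0
        for leaf in self.dtree.leaf_node_iter():
            tip_index[leaf.taxon.label] = next_id
            node_index[id(leaf)] = next_id
            next_id += 1
        n_tips = next_id
        for node in self.dtree.preorder_node_iter():
            if node.is_leaf():
                continue
            node_index[id(node)] = next_id
            next_id += 1
        adj: dict[int, set[int]] = {i: set() for i in range(next_id)}
        for node in self.dtree.preorder_node_iter():
            for child in node.child_nodes():
                u, v = node_index[id(node)], node_index[id(child)]
                adj[u].add(v)
                adj[v].add(u)
        # optionally suppress degree-2 internal nodes (rooting artifacts)
        changed = suppress_degree_two
        while changed:
            changed = False
            for u in list(adj):
                if u >= n_tips and len(adj[u]) == 2:
                    a, b = adj[u]
                    adj[a].discard(u)
                    adj[b].discard(u)
                    adj[a].add(b)
                    adj[b].add(a)
                    del adj[u]
                    changed = True
        # compact renumbering of surviving internal nodes
        internal_ids = sorted(i for i in adj if i >= n_tips)
        remap = {i: i for i in range(n_tips)}
        remap.update({old: n_tips + j for j, old in enumerate(internal_ids)})
        edges = []
        seen = set()
        for u, nbrs in adj.items():
            for v in nbrs:
                key = (min(u, v), max(u, v))
                if key not in seen:
                    seen.add(key)
                    edges.append((remap[u], remap[v]))
        return tip_index, edges, n_tips + len(internal_ids)

    def internal_labels(self) -> dict[int, str]:
        """Map ``id(node)`` -> label for internal nodes.

        Labels ``node_1, node_2, ...`` follow preorder, matching the
        internal-node order of :meth:`adjacency`.
        """
        labels: dict[int, str] = {}
        counter = 0
        for node in self.dtree.preorder_node_iter():
            if node.is_leaf():
                continue
            counter += 1
            labels[id(node)] = f"node_{counter}"
        return labels

    @classmethod
    def from_newick(cls, newick: str) -> "PhylogeneticTree":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(dtree)


def read_tree(path: PathLike, taxa: Sequence[str]) -> PhylogeneticTree:
    """Read a newick or NEXUS tree and reconcile its tips with ``taxa``.

    All branch lengths are replaced by 1. Any taxon missing from the tree, or
    tip missing from ``taxa``, raises :class:`TreeReconciliationError` listing
    both sides of the mismatch. Matching is case-sensitive after whitespace
    trimming.
    """
    text = Path(path).read_text()
    schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    dtree = dendropy.Tree.get(data=text, schema=schema, preserve_underscores=True)
    tree = PhylogeneticTree(dtree)
    taxa_set = {t.strip() for t in taxa}
    tips = {t.strip() for t in tree.tip_labels}
    missing_from_tree = sorted(taxa_set - tips)
    unmatched_tips = sorted(tips - taxa_set)
    if missing_from_tree or unmatched_tips:
        raise TreeReconciliationError(
            f"taxa without a tip: {missing_from_tree}; "
            f"tips without a taxon: {unmatched_tips}"
        )
    return tree


# ---------------------------------------------------------------------------
# Group tables
# ---------------------------------------------------------------------------

def read_groups(path: PathLike, dataset: ShapeDataset) -> ShapeDataset:
    """Attach diet/locomotion labels from a delimited table to a dataset.

    The table needs a ``specimen_id`` or ``taxon`` key column plus ``diet``
    and ``locomotion`` columns drawn from the closed vocabularies. Specimens
    absent from the table are flagged ``ungrouped`` (this is how taxa of
    unknown ecology, like the fossil, stay in the shape analysis but out of
    the classification fits).
    """
    table = pd.read_csv(path, sep=None, engine="python", comment="#")
    table.columns = [c.strip().lower() for c in table.columns]
    if "specimen_id" in table.columns:
        key_col = "specimen_id"
    elif "taxon" in table.columns:
        key_col = "taxon"
    else:
        raise ValueError(f"{path}: need a 'specimen_id' or 'taxon' column")
    for col in ("diet", "locomotion"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing column {col!r}")

    diet_map: dict[str, str] = {}
    loco_map: dict[str, str] = {}
    taxon_map: dict[str, str] = {}
    for _, row in table.iterrows():
        key = str(row[key_col]).strip()
        if key_col == "specimen_id" and "taxon" in table.columns:
            taxon_map[key] = str(row["taxon"]).strip()
        diet = str(row["diet"]).strip()
        loco = str(row["locomotion"]).strip()
        if diet not in DIET_GROUPS:
            raise VocabularyError(
                f"{path}: unknown diet {diet!r}; allowed: {DIET_GROUPS}"
            )
        if loco not in LOCOMOTION_GROUPS:
            raise VocabularyError(
                f"{path}: unknown locomotion {loco!r}; allowed: {LOCOMOTION_GROUPS}"
            )
        diet_map[key] = diet
        loco_map[key] = loco

    if taxon_map:
        dataset = attach_taxa(dataset, taxon_map)
    diets, locos = [], []
    for s in dataset.specimens:
        key = s.specimen_id.strip() if key_col == "specimen_id" else s.taxon.strip()
        diets.append(diet_map.get(key, "ungrouped"))
        locos.append(loco_map.get(key, "ungrouped"))
    return dataset.with_labels(diets, locos)


def attach_taxa(dataset: ShapeDataset, taxon_of: Mapping[str, str]) -> ShapeDataset:
    """Assign taxon labels by specimen id (exact match after trimming)."""
    from dataclasses import replace

    new = []
    for s in dataset.specimens:
        taxon = taxon_of.get(s.specimen_id.strip(), s.taxon)
        new.append(replace(s, taxon=taxon))
    return ShapeDataset(specimens=new)
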