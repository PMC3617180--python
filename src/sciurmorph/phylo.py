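"""Squared-change parsimony on shape data, phylogenetic signal, homoplasy.

Ancestral shapes minimize the summed squared change over the edges of the
(unit-branch-length) tree; the minimizer solves a sparse linear system in
which every internal node is the average of its tree neighbors, coordinate
by coordinate. The minimized sum is the morphometric tree length: small
length relative to tip-permuted trees indicates phylogenetic signal.

Homoplasy is quantified against the best and worst attainable lengths: the
globally minimal length over all unrooted binary topologies (the Steiner
tree problem, solved exhaustively for small taxon counts) and the star-tree
length. SCI = min/observed, SRI = (max-observed)/(max-min).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .io import PhylogeneticTree

__all__ = [
    "AncestralStates",
    "SignalTest",
    "HomoplasyIndices",
    "reconstruct_ancestral_shapes",
    "permutation_signal_test",
    "homoplasy_indices",
    "optimized_tree_length",
    "star_tree_length",
    "enumerate_unrooted_topologies",
]


# ---------------------------------------------------------------------------
# core linear algebra on an edge-list topology
# ---------------------------------------------------------------------------

def _internal_system(
    edges: Sequence[tuple[int, int]], n_nodes: int, n_tips: int
) -> tuple[np.ndarray, np.ndarray]:
    """Build (A, S): A x_int = S @ tip_values at the squared-change optimum.

    A is the internal-node Laplacian block (deg on the diagonal, -1 for
    internal-internal edges); S picks up tip neighbors.
    """
    n_int = n_nodes - n_tips
    A = np.zeros((n_int, n_int))
    S = np.zeros((n_int, n_tips))
    for u, v in edges:
        for a, b in ((u, v), (v, u)):
            if a >= n_tips:
                i = a - n_tips
                A[i, i] += 1.0
                if b >= n_tips:
                    A[i, b - n_tips] -= 1.0
                else:
                    S[i, b] += 1.0
    return A, S


def _solve_states(
    edges: Sequence[tuple[int, int]],
    n_nodes: int,
    tip_values: np.ndarray,
) -> np.ndarray:
    """All node states (tips then internals) at the squared-change optimum."""
    n_tips = tip_values.shape[0]
    if n_nodes == n_tips:  # no internal nodes (2-tip tree)
        return tip_values.copy()
    A, S = _internal_system(edges, n_nodes, n_tips)
    internal = np.linalg.solve(A, S @ tip_values)
    return np.vstack([tip_values, internal])


def _length(edges: Sequence[tuple[int, int]], states: np.ndarray) -> float:
    diffs = states[[u for u, _ in edges]] - states[[v for _, v in edges]]
    return float(np.sum(diffs**2))


def optimized_tree_length(
    edges: Sequence[tuple[int, int]], n_nodes: int, tip_values: np.ndarray
) -> float:
    """Minimized summed squared change for one topology."""
    states = _solve_states(edges, n_nodes, tip_values)
    return _length(edges, states)


def star_tree_length(tip_values: np.ndarray) -> float:
    """Length of the single-internal-node (star) tree: sum of squared deviations
    of the tips from their mean."""
    centered = tip_values - tip_values.mean(axis=0)
    return float(np.sum(centered**2))


# ---------------------------------------------------------------------------
# ancestral shapes on an observed tree
# ---------------------------------------------------------------------------

@dataclass
class AncestralStates:
    """Squared-change-parsimony node shapes and the resulting tree length."""

    tip_index: dict[str, int]
    edges: list[tuple[int, int]]
    states: np.ndarray  # (n_nodes, d); tips first, internals after
    tree_length: float
    node_labels: list[str]  # parallel to states rows

    @property
    def n_tips(self) -> int:
        return len(self.tip_index)

    def internal_shapes(self) -> dict[str, np.ndarray]:
        return {
            self.node_labels[i]: self.states[i]
            for i in range(self.n_tips, self.states.shape[0])
        }

    def labeled_edges(self) -> list[tuple[str, str]]:
        return [(self.node_labels[u], self.node_labels[v]) for u, v in self.edges]


def _tip_matrix(
    tip_index: Mapping[str, int], tip_shapes: Mapping[str, np.ndarray]
) -> np.ndarray:
    missing = sorted(set(tip_index) - set(tip_shapes))
    extra = sorted(set(tip_shapes) - set(tip_index))
    if missing or extra:
        raise ValueError(
            f"tips without shapes: {missing}; shapes without tips: {extra}"
        )
    rows = [None] * len(tip_index)
    for label, idx in tip_index.items():
        rows[idx] = np.asarray(tip_shapes[label], dtype=float).reshape(-1)
    return np.stack(rows)


def reconstruct_ancestral_shapes(
    tree: PhylogeneticTree, tip_shapes: Mapping[str, np.ndarray]
) -> AncestralStates:
    """Reconstruct internal-node shapes by squared-change parsimony.

    Each internal node solves to the mean of its tree neighbors (unit branch
    lengths); the solution is unique on a connected tree, and the summed
    squared change over edges is the tree length.
    """
    tip_index, edges, n_nodes = tree.adjacency()
    V = _tip_matrix(tip_index, tip_shapes)
    states = _solve_states(edges, n_nodes, V)
    labels = [None] * n_nodes
    for lab, i in tip_index.items():
        labels[i] = lab
    for j in range(len(tip_index), n_nodes):
        labels[j] = f"node_{j - len(tip_index) + 1}"
    return AncestralStates(
        tip_index=dict(tip_index),
        edges=list(edges),
        states=states,
        tree_length=_length(edges, states),
        node_labels=labels,
    )


# ---------------------------------------------------------------------------
# permutation test for phylogenetic signal
# ---------------------------------------------------------------------------

@dataclass
class SignalTest:
    observed_length: float
    permuted_lengths: np.ndarray
    p_value: float
    n_perm: int
    seed: int


def permutation_signal_test(
    tree: PhylogeneticTree,
    tip_shapes: Mapping[str, np.ndarray],
    n_perm: int = 9999,
    seed: int = 0,
) -> SignalTest:
    """Permutation test of phylogenetic signal in shape data.

    The null of no phylogenetic structure is simulated by shuffling the
    tip-to-shape assignment; the rejection tail is small tree lengths,
    p = (1 + #{permuted <= observed}) / (1 + n_perm).
    """
    if tree.n_tips < 4:
        raise ValueError("signal test needs at least 4 tips")
    if n_perm < 99:
        warnings.warn("n_perm < 99 gives a very coarse permutation p", RuntimeWarning)
    tip_index, edges, n_nodes = tree.adjacency()
    n_tips = len(tip_index)
    V = _tip_matrix(tip_index, tip_shapes)
    A, S = _internal_system(edges, n_nodes, n_tips)
    lu = lu_factor(A)

    def length_for(tips: np.ndarray) -> float:
        internal = lu_solve(lu, S @ tips)
        states = np.vstack([tips, internal])
        return _length(edges, states)

    observed = length_for(V)
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    for i in range(n_perm):
        permuted[i] = length_for(V[rng.permutation(n_tips)])
    p = (1 + int(np.sum(permuted <= observed))) / (1 + n_perm)
    return SignalTest(
        observed_length=observed,
        permuted_lengths=permuted,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Steiner search and homoplasy indices
# ---------------------------------------------------------------------------

def enumerate_unrooted_topologies(
    n_tips: int,
) -> Iterator[tuple[list[tuple[int, int]], int]]:
    """Yield every unrooted binary topology on labeled tips 0..n_tips-1.

    Topologies are edge lists over node ids (tips first, internals from
    ``n_tips``); there are (2n-5)!! of them. Generated by inserting each new
    tip into every edge of every smaller topology.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")

    def recurse(edges: list[tuple[int, int]], next_tip: int, next_internal: int):
        if next_tip == n_tips:
            yield list(edges), next_internal
            return
        for i in range(len(edges)):
            u, v = edges[i]
            w = next_internal
            new_edges = edges[:i] + edges[i + 1 :] + [(u, w), (w, v), (w, next_tip)]
            yield from recurse(new_edges, next_tip + 1, next_internal + 1)

    base = [(0, n_tips), (1, n_tips), (2, n_tips)]
    yield from recurse(base, 3, n_tips + 1)


def _unrooted_observed(tree: PhylogeneticTree) -> tuple[dict[str, int], list, int]:
    return tree.adjacency()


def _nni_neighbors(
    edges: list[tuple[int, int]], n_nodes: int, n_tips: int
) -> Iterator[list[tuple[int, int]]]:
    """Nearest-neighbor-interchange moves on an unrooted binary topology."""
    adj: dict[int, set[int]] = {i: set() for i in range(n_nodes)}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    for u, v in edges:
        if u < n_tips or v < n_tips:
            continue  # internal edges only
        a, b = sorted(adj[u] - {v})
        c, d = sorted(adj[v] - {u})
        for swap_u, swap_v in ((b, c), (b, d)):
            new = []
            for x, y in edges:
                e = tuple(sorted((x, y)))
                if e == tuple(sorted((u, swap_u))):
                    new.append((u, swap_v))
                elif e == tuple(sorted((v, swap_v))):
                    new.append((v, swap_u))
                else:
                    new.append((x, y))
            yield new


@dataclass
class HomoplasyIndices:
    min_length: float
    max_length: float
    observed_length: float
    sci: float
    sri: float
    exact: bool  # True when min_length came from exhaustive enumeration
    degenerate: bool  # True when max == min (indices undefined)


def homoplasy_indices(
    tree: PhylogeneticTree,
    tip_shapes: Mapping[str, np.ndarray],
    max_taxa_exhaustive: int = 11,
    heuristic: bool = False,
) -> HomoplasyIndices:
    """Shape consistency (SCI) and retention (SRI) indices.

    ``min_length`` is the Steiner optimum: the smallest optimized tree length
    over all unrooted binary topologies, found by exhaustive enumeration for
    up to ``max_taxa_exhaustive`` taxa (the (2n-5)!! explosion forbids more).
    ``max_length`` is the star-tree length. Above the cap, pass
    ``heuristic=True`` for a nearest-neighbor-interchange descent from the
    observed topology; the result is then labeled approximate.
    """
    # observed length on the unrooted topology: the Steiner enumeration is
    # over unrooted trees, so the comparison must drop the degree-2 root
    # (which would otherwise halve one edge's contribution)
    tip_index, obs_edges, obs_n_nodes = tree.adjacency(suppress_degree_two=True)
    n_tips = len(tip_index)
    V = _tip_matrix(tip_index, tip_shapes)
    observed = optimized_tree_length(obs_edges, obs_n_nodes, V)
    max_length = star_tree_length(V)

    if n_tips <= max_taxa_exhaustive:
        best = np.inf
        for edges, n_nodes in enumerate_unrooted_topologies(n_tips):
            L = optimized_tree_length(edges, n_nodes, V)
            if L < best:
                best = L
        exact = True
    elif heuristic:
        best, exact = _nni_descent(obs_edges, obs_n_nodes, n_tips, V), False
    else:
        raise ValueError(
            f"{n_tips} taxa exceed the exhaustive-search cap "
            f"({max_taxa_exhaustive}); pass heuristic=True for an approximate "
            f"NNI-descent minimum"
        )

    degenerate = max_length - best < 1e-12
    if degenerate:
        sci = sri = float("nan")
    else:
        sci = best / observed if observed > 0 else 1.0
        sri = (max_length - observed) / (max_length - best)
    return HomoplasyIndices(
        min_length=best,
        max_length=max_length,
        observed_length=observed,
        sci=sci,
        sri=sri,
        exact=exact,
        degenerate=degenerate,
    )


def _nni_descent(
    edges: list[tuple[int, int]], n_nodes: int, n_tips: int, V: np.ndarray
) -> float:
    current_edges, current_n = list(edges), n_nodes
    current = optimized_tree_length(current_edges, current_n, V)
    improved = True
    while improved:
        improved = False
        for cand in _nni_neighbors(current_edges, current_n, n_tips):
            L = optimized_tree_length(cand, current_n, V)
            if L < current - 1e-12:
                current, current_edges = L, cand
                improved = True
                break
    return current
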