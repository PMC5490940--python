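"""Therapy- and tumor-specific subnetworks grown around seed proteins.

Seeds (drug targets of a therapeutic class, or tumor driver genes) whose
induced subgraph is significantly connected are expanded into a specific
subnetwork with the DIAMOnD criterion: at each step the non-member node
with the most significant hypergeometric connectivity to the current set
joins it. Writing N for the interactome size, s for the current set size,
k for a candidate's degree and ks for its links into the set, the score is
the tail probability

    p = P(X >= ks),   X ~ Hypergeometric(population N-1, successes s, draws k).

How many nodes to add is decided by 10-fold cross-validation on the seeds:
held-out seeds are checked for recall along the expansion, and all seeds
are checked for membership in the expanding network's major (seed-richest)
connected component. The expansion is cut at the mean of the flattening
points of the two fold-averaged curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "DiamondStep",
    "diamond_expand",
    "RecallCurves",
    "cv_recall_curves",
    "StoppingPoint",
    "stopping_point",
    "build_subnetwork",
]


@dataclass
class DiamondStep:
    rank: int
    node: object
    k: int
    ks: int
    p_hyper: float


def diamond_expand(graph: nx.Graph, seeds: Iterable, n_add: int) -> list[DiamondStep]:
    """Iterative DIAMOnD expansion of a seed set.

    At each step, candidates are the non-member nodes with at least one
    link to the current set (any other node has p = 1 and can never win).
    The node with the smallest hypergeometric tail p-value is added; ties
    are broken by larger ks, then lexicographically by node id. The added
    node joins the set for subsequent steps (seed weighting 1).
    """
    seeds = set(seeds)
    if not seeds:
        raise ValueError("seeds must be non-empty")
    missing = seeds - set(graph.nodes)
    if missing:
        raise KeyError(f"seeds not in graph: {sorted(map(str, missing))}")
    if n_add < 1:
        raise ValueError("n_add must be >= 1")

    N = graph.number_of_nodes()
    current = set(seeds)
    # links-to-set count per candidate, maintained incrementally
    ks_count: dict = {}
    for s in current:
        for v in graph.neighbors(s):
            if v not in current:
                ks_count[v] = ks_count.get(v, 0) + 1

    steps: list[DiamondStep] = []
    for rank in range(1, n_add + 1):
        if not ks_count:
            break  # nothing left connected to the set
        s_size = len(current)
        scored = []
        for v in ks_count:
            k = graph.degree(v)
            ks = ks_count[v]
            p = float(hypergeom.sf(ks - 1, N - 1, s_size, k))
            scored.append((p, ks, v, k))
        p_min = min(s[0] for s in scored)
        # mathematically tied p-values can differ by floating-point noise
        # across (k, ks) configurations; group them before tie-breaking by
        # larger ks, then lexicographic node id
        tol = 1e-9 * max(p_min, 1e-300)
        tied = [s for s in scored if s[0] <= p_min + tol]
        p, ks, v, k = min(tied, key=lambda s: (-s[1], str(s[2])))
        steps.append(DiamondStep(rank=rank, node=v, k=k, ks=ks, p_hyper=p))
        current.add(v)
        del ks_count[v]
        for w in graph.neighbors(v):
            if w not in current:
                ks_count[w] = ks_count.get(w, 0) + 1
    return steps


@dataclass
class RecallCurves:
    """Fold-averaged diagnostics of a seed cross-validation.

    ``seed_recall[r-1]`` is the mean fraction of held-out seeds recovered
    within the first r DIAMOnD additions; ``lcc_fraction[r-1]`` is the mean
    fraction of all seeds lying in the major (seed-richest) connected
    component of the growing network after r additions. Both curves are
    non-decreasing in rank.
    """

    ranks: np.ndarray
    seed_recall: np.ndarray
    lcc_fraction: np.ndarray


def _major_component_seed_fraction(graph: nx.Graph, members: set, seeds: set) -> float:
    sub = graph.subgraph(members)
    if sub.number_of_nodes() == 0:
        return 0.0
    best = 0
    for comp in nx.connected_components(sub):
        best = max(best, len(comp & seeds))
    return best / len(seeds)


def cv_recall_curves(
    graph: nx.Graph,
    seeds: Iterable,
    folds: int = 10,
    n_add_max: int = 50,
    rng_seed: int | np.random.Generator = 0,
) -> RecallCurves:
    """Cross-validated recall diagnostics of DIAMOnD expansion.

    Seeds are shuffled and split into ``folds`` partitions; each fold is
    held out in turn, the expansion runs from the retained seeds, and the
    held-out recall and major-component curves are recorded and averaged.
    """
    seeds = sorted(set(seeds), key=str)
    if folds > len(seeds):
        raise ValueError(f"folds ({folds}) exceeds number of seeds ({len(seeds)})")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    perm = rng.permutation(len(seeds))
    partitions = np.array_split(perm, folds)
    all_seeds = set(seeds)

    recall = np.zeros(n_add_max)
    lcc = np.zeros(n_add_max)
    for part in partitions:
        held = {seeds[i] for i in part}
        retained = all_seeds - held
        steps = diamond_expand(graph, retained, n_add_max)
        members = set(retained)
        recalled = 0
        for r in range(1, n_add_max + 1):
            if r <= len(steps):
                node = steps[r - 1].node
                members.add(node)
                if node in held:
                    recalled += 1
            recall[r - 1] += recalled / len(held)
            lcc[r - 1] += _major_component_seed_fraction(graph, members, all_seeds)
    recall /= folds
    lcc /= folds
    return RecallCurves(ranks=np.arange(1, n_add_max + 1), seed_recall=recall, lcc_fraction=lcc)


@dataclass
class StoppingPoint:
    rank: int
    flattening_ranks: tuple[int, int]
    warning: bool


def _flattening_rank(curve: np.ndarray, window: int, slope_tol: float) -> tuple[int, bool]:
    """Smallest rank whose mean forward increment over `window` ranks < tol.

    Near the end of the curve the forward window is truncated. If the curve
    never flattens, the last rank is returned with a warning.
    """
    L = len(curve)
    for i in range(L - 1):
        j = min(i + window, L - 1)
        slope = (curve[j] - curve[i]) / (j - i)
        if slope < slope_tol:
            return i + 1, False
    return L, True


def stopping_point(
    curves: RecallCurves, window: int = 10, slope_tol: float = 0.002
) -> StoppingPoint:
    """Cut rank: the mean of the flattening points of the two recall curves."""
    if len(curves.ranks) == 0:
        raise ValueError("empty curves")
    r1, w1 = _flattening_rank(np.asarray(curves.seed_recall, dtype=float), window, slope_tol)
    r2, w2 = _flattening_rank(np.asarray(curves.lcc_fraction, dtype=float), window, slope_tol)
    return StoppingPoint(rank=round((r1 + r2) / 2), flattening_ranks=(r1, r2), warning=w1 or w2)


def build_subnetwork(graph: nx.Graph, seeds: Iterable, n: int) -> nx.Graph:
    """Induced subgraph on the seeds plus the first n DIAMOnD additions."""
    if n < 0:
        raise ValueError("n must be >= 0")
    seeds = set(seeds)
    members = set(seeds)
    if n > 0:
        steps = diamond_expand(graph, seeds, n)
        members |= {s.node for s in steps}
    return graph.subgraph(members).copy()
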