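"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive results from first principles (exhaustive
subset enumeration, explicit hypergeometric sums) without touching the
library's own code paths, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import networkx as nx


def brute_force_groups(similar_table, max_size: int = 5) -> set[frozenset]:
    """All protein subsets qualifying as anchor-star groups, by exhaustion.

    A subset S (2 <= |S| <= max_size) qualifies if some cavity c of a
    member p is similar to at least one cavity of every other member of S.
    Enumerates every subset and every candidate anchor cavity directly
    from the similar-pair table.
    """
    # cavity -> set of proteins owning a cavity similar to it
    similar_to: dict[str, set[str]] = {}
    proteins = set()
    for row in similar_table.pairs.itertuples():
        pa = similar_table.protein_of(row.cavity_a)
        pb = similar_table.protein_of(row.cavity_b)
        proteins |= {pa, pb}
        if pa != pb:
            similar_to.setdefault(row.cavity_a, set()).add(pb)
            similar_to.setdefault(row.cavity_b, set()).add(pa)
    owner = {c: similar_table.protein_of(c) for c in similar_to}

    qualifying = set()
    proteins = sorted(proteins)
    for size in range(2, max_size + 1):
        for subset in itertools.combinations(proteins, size):
            s = set(subset)
            for c, partners in similar_to.items():
                p = owner[c]
                if p in s and (s - {p}) <= partners:
                    qualifying.add(frozenset(s))
                    break
    return qualifying


def hypergeom_right_tail(ks: int, N: int, K: int, k: int) -> Fraction:
    """P(X >= ks) for X ~ Hypergeometric(population N, successes K, draws k).

    Explicit term-by-term summation of the pmf in exact rational
    arithmetic, so tie detection is not at the mercy of floating point.
    """
    denom = comb(N, k)
    hi = min(k, K)
    total = 0
    for i in range(max(ks, 0), hi + 1):
        total += comb(K, i) * comb(N - K, k - i)
    return Fraction(total, denom)


def assert_diamond_matches_enumeration(graph: nx.Graph, seeds: set, steps) -> None:
    """Check a DIAMOnD expansion against exhaustive per-step enumeration.

    At every step, all non-member nodes are scored with the exact
    hypergeometric tail; the node the expansion added must attain the
    minimal (p, -ks) key (several nodes may tie that exact key, in which
    case any of them is acceptable — the expansion's deterministic
    lexicographic tie-break is covered by a dedicated unit test).
    """
    N = graph.number_of_nodes()
    current = set(seeds)
    for step in steps:
        scored = {}
        for v in graph.nodes:
            if v in current:
                continue
            k = graph.degree(v)
            ks = sum(1 for w in graph.neighbors(v) if w in current)
            scored[v] = (hypergeom_right_tail(ks, N - 1, len(current), k), -ks)
        best_key = min(scored.values())
        assert scored[step.node] == best_key, (
            f"rank {step.rank}: added {step.node} with exact key "
            f"{scored[step.node]}, but minimum is {best_key}"
        )
        current.add(step.node)
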