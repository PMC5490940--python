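"""From cavity-pair similarity scores to candidate multi-target groups.

Binding cavities detected in protein structures are compared all-vs-all by
an external tool that emits a similarity score in [0, 1] per cavity pair.
Pairs scoring strictly above a threshold (default 0.6) are classified as
*similar*; everything downstream consumes only this classification.

A *polypharmacology group* is a set of 2-5 proteins anchored by a single
cavity: one member owns a cavity that is similar to at least one cavity of
every other member, so a single ligand fitting the anchor cavity could in
principle engage the whole group. Group enumeration walks every cavity as
a candidate anchor and emits all qualifying protein subsets, deduplicating
identical protein sets across anchors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import math

import networkx as nx
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher

__all__ = [
    "CavityRecord",
    "CavitySimilarityTable",
    "classify_similar",
    "ProteinGraphResult",
    "build_protein_graph",
    "PolypharmGroup",
    "enumerate_groups",
    "fisher_enrichment",
]


@dataclass(frozen=True)
class CavityRecord:
    cavity_id: str
    protein_id: str
    structure_id: str = ""
    chain: str = ""


@dataclass
class CavitySimilarityTable:
    """Scored cavity pairs plus the cavity -> protein mapping.

    Pairs are unordered and stored once with ``cavity_a < cavity_b``
    lexicographically; duplicate entries keep the maximum score. Scores
    must lie in [0, 1].
    """

    pairs: pd.DataFrame
    cavity_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.pairs
        required = {"cavity_a", "cavity_b", "score"}
        if not required <= set(df.columns):
            raise ValueError(f"pairs table needs columns {sorted(required)}")
        if len(df) and ((df["score"] < 0) | (df["score"] > 1)).any():
            raise ValueError("scores must lie in [0, 1]")
        a = df["cavity_a"].astype(str)
        b = df["cavity_b"].astype(str)
        lo, hi = a.where(a < b, b), b.where(a < b, a)
        df = df.assign(cavity_a=lo, cavity_b=hi)
        df = df[df["cavity_a"] != df["cavity_b"]]
        df = (
            df.sort_values("score", ascending=False)
            .drop_duplicates(["cavity_a", "cavity_b"], keep="first")
            .sort_values(["cavity_a", "cavity_b"], ignore_index=True)
        )
        self.pairs = df

    def __len__(self) -> int:
        return len(self.pairs)

    def protein_of(self, cavity_id: str) -> str:
        rec = self.cavity_map.get(cavity_id)
        if rec is None:
            raise KeyError(f"cavity {cavity_id!r} has no protein mapping")
        return rec.protein_id

    # --- TSV round trip ----------------------------------------------------

    def write(self, pairs_path, map_path) -> None:
        self.pairs.to_csv(pairs_path, sep="\t", index=False)
        rows = [
            {"cavity_id": r.cavity_id, "protein_id": r.protein_id,
             "structure_id": r.structure_id, "chain": r.chain}
            for r in self.cavity_map.values()
        ]
        pd.DataFrame(rows).sort_values("cavity_id").to_csv(map_path, sep="\t", index=False)

    @classmethod
    def read(cls, pairs_path, map_path) -> "CavitySimilarityTable":
        pairs = pd.read_csv(pairs_path, sep="\t", dtype={"cavity_a": str, "cavity_b": str})
        mp = pd.read_csv(map_path, sep="\t", dtype=str).fillna("")
        cavity_map = {
            row.cavity_id: CavityRecord(row.cavity_id, row.protein_id,
                                        row.structure_id, row.chain)
            for row in mp.itertuples()
        }
        return cls(pairs=pairs, cavity_map=cavity_map)


def classify_similar(table: CavitySimilarityTable, threshold: float = 0.6) -> CavitySimilarityTable:
    """Keep cavity pairs scoring strictly above the similarity threshold.

    The default 0.6 is the recommended operating point of the upstream
    cavity-comparison score; "above" is read strictly, so a pair at exactly
    the threshold is dropped. Raising the threshold can only remove pairs.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    kept = table.pairs[table.pairs["score"] > threshold].reset_index(drop=True)
    return CavitySimilarityTable(pairs=kept, cavity_map=table.cavity_map)


@dataclass
class ProteinGraphResult:
    """Protein-level cross-pharmacology graph with cavity-pair counts."""

    graph: nx.Graph
    n_intra: int
    n_inter: int

    @property
    def intra_fraction(self) -> float:
        total = self.n_intra + self.n_inter
        return self.n_intra / total if total else float("nan")


def build_protein_graph(similar: CavitySimilarityTable) -> ProteinGraphResult:
    """Collapse similar cavity pairs onto proteins.

    Cavity pairs within one protein are counted as intra-protein (they
    create no edge); pairs across proteins add weight to the corresponding
    protein edge (weight = number of similar cavity pairs). An unmapped
    cavity id raises a KeyError naming it.
    """
    g = nx.Graph()
    for rec in similar.cavity_map.values():
        g.add_node(rec.protein_id)
    n_intra = n_inter = 0
    for row in similar.pairs.itertuples():
        pa = similar.protein_of(row.cavity_a)
        pb = similar.protein_of(row.cavity_b)
        if pa == pb:
            n_intra += 1
            continue
        n_inter += 1
        if g.has_edge(pa, pb):
            g[pa][pb]["weight"] += 1
        else:
            g.add_edge(pa, pb, weight=1)
    return ProteinGraphResult(graph=g, n_intra=n_intra, n_inter=n_inter)


@dataclass(frozen=True)
class PolypharmGroup:
    """2-5 proteins that could share a ligand via one anchor cavity."""

    proteins: frozenset
    anchor_cavity: str
    min_pair_score: float

    def __post_init__(self) -> None:
        if not 2 <= len(self.proteins) <= 5:
            raise ValueError("group must contain 2-5 proteins")


def enumerate_groups(
    similar: CavitySimilarityTable,
    max_size: int = 5,
    restrict_to: Iterable | None = None,
) -> list[PolypharmGroup]:
    """Enumerate anchor-star polypharmacology groups from similar pairs.

    For each cavity c of protein p, let N(c) be the other proteins with at
    least one cavity similar to c (pre-filtered to ``restrict_to`` when
    given, to avoid combinatorial blow-up outside the network of
    interest). Every subset {p} | T with non-empty T a subset of N(c) and
    group size <= max_size is emitted. The per-member score is the best
    anchor-vs-member cavity score; the group's ``min_pair_score`` is the
    weakest member. Identical protein sets arising from several anchors
    keep the anchor with the highest min_pair_score (ties: lexicographic
    smallest anchor id).
    """
    if not 2 <= max_size <= 5:
        raise ValueError("max_size must be in [2, 5]")
    restrict = set(restrict_to) if restrict_to is not None else None

    # anchor cavity -> {other protein: best score vs anchor}
    neighbors: dict[str, dict[str, float]] = {}
    for row in similar.pairs.itertuples():
        pa = similar.protein_of(row.cavity_a)
        pb = similar.protein_of(row.cavity_b)
        if pa == pb:
            continue
        for anchor, other_protein in ((row.cavity_a, pb), (row.cavity_b, pa)):
            if restrict is not None and other_protein not in restrict:
                continue
            d = neighbors.setdefault(anchor, {})
            if row.score > d.get(other_protein, -1.0):
                d[other_protein] = row.score

    best: dict[frozenset, PolypharmGroup] = {}
    for anchor, nb in neighbors.items():
        p = similar.protein_of(anchor)
        if restrict is not None and p not in restrict:
            continue
        others = sorted(nb)
        for r in range(1, max_size):
            for combo in itertools.combinations(others, r):
                proteins = frozenset((p,) + combo)
                if len(proteins) != r + 1:
                    continue
                score = min(nb[q] for q in combo)
                group = PolypharmGroup(proteins, anchor, score)
                prev = best.get(proteins)
                if (
                    prev is None
                    or group.min_pair_score > prev.min_pair_score
                    or (group.min_pair_score == prev.min_pair_score
                        and group.anchor_cavity < prev.anchor_cavity)
                ):
                    best[proteins] = group
    return sorted(
        best.values(), key=lambda g: (-g.min_pair_score, sorted(g.proteins), g.anchor_cavity)
    )


def groups_to_frame(groups: Iterable[PolypharmGroup]) -> pd.DataFrame:
    """One group per row: semicolon-joined proteins, anchor, min score."""
    return pd.DataFrame(
        [
            {
                "proteins": ";".join(sorted(g.proteins)),
                "anchor_cavity": g.anchor_cavity,
                "min_pair_score": g.min_pair_score,
            }
            for g in groups
        ]
    )


def fisher_enrichment(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Odds ratio and right-tailed Fisher exact p of a 2x2 table [[a,b],[c,d]].

    OR = (a*d)/(b*c), with inf when b*c = 0 and a*d > 0 and 0 when
    a*d = 0 with b*c > 0; p is the hypergeometric right tail P(X >= a).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("table total must be positive")
    ad, bc = a * d, b * c
    if bc == 0:
        odds = math.inf if ad > 0 else math.nan
    else:
        odds = ad / bc
    _, p = _scipy_fisher([[a, b], [c, d]], alternative="greater")
    return odds, float(p)
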