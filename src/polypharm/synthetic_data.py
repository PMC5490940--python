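"""Synthetic inputs with the statistical structure the pipeline assumes.

Every input the analysis consumes — the interactome, seed modules, the
cavity-pair similarity table, per-protein ligand sets and the paired
cancer/healthy metabolic models — can be generated here with *planted*
structure, so each downstream stage has an end-to-end parameter-recovery
test: planted cavity groups are recovered by group enumeration, planted
seed modules reach percolation significance, planted shared-scaffold
ligand pairs reach E-value significance, and the planted redundant-pathway
gene pair is the unique genuine co-inhibition in the toy model pair.

All generators are deterministic under a fixed seed. The interactome uses
preferential attachment because the diffusion-based screening presumes the
hub-dominated topology of real protein interaction networks; a
configuration-model alternative is available. Background cavity scores
follow a truncated normal centered well below the similarity threshold,
emulating the empirical all-vs-all score mass. Ligands are fixed-length
bitset fingerprints built from a universe of shared scaffold patterns plus
per-molecule noise, so random set pairs produce the size-dependent,
right-skewed raw-score background the calibration expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cavity_space import CavityRecord, CavitySimilarityTable
from .ligand_sea import FingerprintSet
from .metabolic_screen import MetabolicModel, Reaction

__all__ = [
    "SyntheticSpec",
    "gen_interactome",
    "PlantedModule",
    "plant_seed_module",
    "gen_cavity_scores",
    "ScaffoldUniverse",
    "LigandSets",
    "gen_ligand_sets",
    "gen_toy_models",
]


@dataclass
class SyntheticSpec:
    """Bundle of generator parameters for a full synthetic study."""

    n_proteins: int = 150
    mean_degree: int = 4
    n_seeds: int = 12
    planted_group_sizes: tuple = (3, 2)
    noise_sd: float = 0.08
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seeds > self.n_proteins:
            raise ValueError("n_seeds must not exceed n_proteins")
        if self.mean_degree >= self.n_proteins:
            raise ValueError("mean_degree must be below n_proteins")
        for s in self.planted_group_sizes:
            if not 2 <= s <= 5:
                raise ValueError("planted group sizes must lie in [2, 5]")


def _protein_id(i: int) -> str:
    return f"P{i:04d}"


def gen_interactome(
    n_nodes: int,
    mean_degree: int,
    rng_seed: int,
    model: str = "preferential_attachment",
) -> nx.Graph:
    """Generate a simple connected protein interaction network.

    The default preferential-attachment model yields the heavy-tailed,
    hub-dominated degree distribution of curated interactomes. The
    ``configuration`` alternative draws a power-law degree sequence,
    simplifies the multigraph and keeps the largest component (so it may
    return slightly fewer than ``n_nodes`` nodes).
    """
    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    if mean_degree < 2:
        raise ValueError("mean_degree must be >= 2")
    if mean_degree >= n_nodes:
        raise ValueError("mean_degree must be below n_nodes")
    seed = int(rng_seed)
    if model == "preferential_attachment":
        m = max(1, mean_degree // 2)
        g = nx.barabasi_albert_graph(n_nodes, m, seed=seed)
    elif model == "configuration":
        rng = np.random.default_rng(seed)
        degs = np.clip(rng.zipf(2.5, size=n_nodes), 1, n_nodes - 1)
        if degs.sum() % 2:
            degs[0] += 1
        mg = nx.configuration_model(degs.tolist(), seed=seed)
        g = nx.Graph(mg)
        g.remove_edges_from(nx.selfloop_edges(g))
        largest = max(nx.connected_components(g), key=len)
        g = g.subgraph(largest).copy()
        g = nx.convert_node_labels_to_integers(g)
    else:
        raise ValueError(f"unknown interactome model {model!r}")
    return nx.relabel_nodes(g, {i: _protein_id(i) for i in g.nodes})


@dataclass
class PlantedModule:
    """A connected seed module planted into an interactome."""

    graph: nx.Graph  # interactome including any extra planted edges
    seeds: frozenset
    added_edges: list = field(default_factory=list)


def plant_seed_module(
    graph: nx.Graph,
    size: int,
    extra_edge_prob: float = 0.5,
    rng_seed: int | np.random.Generator = 0,
) -> PlantedModule:
    """Plant a connected seed set, densifying it with extra edges.

    A connected node set is grown by a random neighbor walk; then each
    missing within-set edge is added with probability ``extra_edge_prob``
    (1.0 turns the set into a clique). The input graph is not modified;
    the returned module carries the augmented graph and the added edges.
    """
    if size > graph.number_of_nodes():
        raise ValueError("module size exceeds graph size")
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    nodes = sorted(graph.nodes)
    start = nodes[rng.integers(len(nodes))]
    chosen = {start}
    frontier = set(graph.neighbors(start))
    while len(chosen) < size:
        if not frontier:  # should not happen on a connected graph
            rest = [v for v in nodes if v not in chosen]
            frontier = {rest[rng.integers(len(rest))]}
        pick = sorted(frontier)[rng.integers(len(frontier))]
        chosen.add(pick)
        frontier |= set(graph.neighbors(pick))
        frontier -= chosen
    out = graph.copy()
    added = []
    members = sorted(chosen)
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            if not out.has_edge(a, b) and rng.random() < extra_edge_prob:
                out.add_edge(a, b)
                added.append((a, b))
    return PlantedModule(graph=out, seeds=frozenset(chosen), added_edges=added)


def gen_cavity_scores(
    proteins: list[str],
    cavities_per_protein: int = 2,
    planted_groups: list | None = None,
    theta_high: float = 0.8,
    noise_sd: float = 0.08,
    rng_seed: int | np.random.Generator = 0,
) -> CavitySimilarityTable:
    """All-vs-all cavity scores with planted similarity groups.

    Background pair scores are truncated normal(0.2, noise_sd) clipped to
    [0, 1], massing far below the 0.6 similarity threshold. For each
    planted protein group, one anchor cavity of the first member is given
    a score drawn uniformly from [theta_high, 1] against one cavity of
    every other member, so anchor-star group enumeration recovers it.
    """
    if planted_groups:
        for grp in planted_groups:
            unknown = set(grp) - set(proteins)
            if unknown:
                raise ValueError(f"planted group members not in proteins: {sorted(unknown)}")
    if not 0 < theta_high <= 1:
        raise ValueError("theta_high must be in (0, 1]")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed

    cavity_map = {}
    cavities = []
    for p in proteins:
        for j in range(cavities_per_protein):
            cid = f"{p}_c{j}"
            cavity_map[cid] = CavityRecord(cavity_id=cid, protein_id=p,
                                           structure_id=f"{p}_s0", chain="A")
            cavities.append(cid)

    n = len(cavities)
    iu = np.triu_indices(n, k=1)
    scores = np.clip(rng.normal(0.2, noise_sd, size=len(iu[0])), 0.0, 1.0)
    a = [cavities[i] for i in iu[0]]
    b = [cavities[j] for j in iu[1]]
    df = pd.DataFrame({"cavity_a": a, "cavity_b": b, "score": scores})
    key = {}
    for idx, (ca, cb) in enumerate(zip(a, b)):
        key[(min(ca, cb), max(ca, cb))] = idx

    if planted_groups:
        for grp in planted_groups:
            grp = list(grp)
            anchor = f"{grp[0]}_c0"
            for q in grp[1:]:
                other = f"{q}_c0"
                pair = (min(anchor, other), max(anchor, other))
                df.loc[key[pair], "score"] = rng.uniform(theta_high, 1.0)
    return CavitySimilarityTable(pairs=df, cavity_map=cavity_map)


@dataclass
class ScaffoldUniverse:
    """A clustered chemical universe: scaffold bit patterns plus noise.

    Each ligand is one of ``n_scaffolds`` base patterns with a few bits
    flipped, so two ligands from the same scaffold have Tanimoto ~0.7
    while cross-scaffold pairs sit near 0. Random set pairs then collide
    on scaffolds at a Poisson-like rate, producing the right-skewed,
    size-dependent raw-score background that real compound libraries show.
    """

    n_bits: int = 1024
    n_scaffolds: int = 100
    bits_per_scaffold: int = 100
    n_flips: int = 8
    rng_seed: int = 0
    scaffolds: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.rng_seed)
        self.scaffolds = np.zeros((self.n_scaffolds, self.n_bits), dtype=bool)
        for i in range(self.n_scaffolds):
            on = rng.choice(self.n_bits, size=self.bits_per_scaffold, replace=False)
            self.scaffolds[i, on] = True

    def ligand(self, scaffold_idx: int, rng: np.random.Generator) -> np.ndarray:
        fp = self.scaffolds[scaffold_idx].copy()
        on = np.flatnonzero(fp)
        off = np.flatnonzero(~fp)
        drop = rng.choice(on, size=min(self.n_flips, len(on)), replace=False)
        add = rng.choice(off, size=min(self.n_flips, len(off)), replace=False)
        fp[drop] = False
        fp[add] = True
        return fp

    def draw_ligands(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n random ligands, each from a uniformly chosen scaffold."""
        idx = rng.integers(0, self.n_scaffolds, size=n)
        return np.stack([self.ligand(i, rng) for i in idx])


@dataclass
class LigandSets:
    sets: dict  # protein_id -> FingerprintSet
    shared_pairs: list  # planted (protein_a, protein_b) sharing a scaffold
    universe: ScaffoldUniverse


def gen_ligand_sets(
    n_proteins: int,
    set_size_range: tuple[int, int] = (5, 20),
    n_shared_scaffold_pairs: int = 2,
    rng_seed: int = 0,
    universe: ScaffoldUniverse | None = None,
    shared_fraction: float = 0.9,
) -> LigandSets:
    """Per-protein ligand fingerprint sets with planted shared-scaffold pairs.

    Most proteins draw their ligands uniformly from the scaffold universe.
    Designated pairs instead draw ``shared_fraction`` of their ligands
    from one common scaffold, producing many cross-pairs with Tc > 0.55
    and hence raw scores far above the size-matched background.
    """
    lo, hi = set_size_range
    if lo < 1:
        raise ValueError("set sizes must be >= 1")
    if 2 * n_shared_scaffold_pairs > n_proteins:
        raise ValueError("not enough proteins for the requested shared pairs")
    rng = np.random.default_rng(rng_seed)
    universe = universe or ScaffoldUniverse(rng_seed=rng_seed)
    proteins = [f"L{i:04d}" for i in range(n_proteins)]

    shared_pairs = []
    shared_scaffold = {}
    for i in range(n_shared_scaffold_pairs):
        a, b = proteins[2 * i], proteins[2 * i + 1]
        scaf = int(rng.integers(universe.n_scaffolds))
        shared_pairs.append((a, b))
        shared_scaffold[a] = scaf
        shared_scaffold[b] = scaf

    sets = {}
    for p in proteins:
        n = int(rng.integers(lo, hi + 1))
        if p in shared_scaffold:
            n_core = max(1, int(round(shared_fraction * n)))
            core = np.stack([universe.ligand(shared_scaffold[p], rng) for _ in range(n_core)])
            rest = universe.draw_ligands(n - n_core, rng) if n > n_core else None
            fps = core if rest is None else np.vstack([core, rest])
        else:
            fps = universe.draw_ligands(n, rng)
        sets[p] = FingerprintSet(protein_id=p, fingerprints=fps)
    return LigandSets(sets=sets, shared_pairs=shared_pairs, universe=universe)


def gen_toy_models(rng_seed: int = 0) -> tuple[MetabolicModel, MetabolicModel]:
    """Paired cancer/healthy toy metabolic models with a planted gene pair.

    Both models share stoichiometry and GPR rules and differ only in flux
    bounds. Glucose is taken up and converted to pyruvate through two
    redundant gene-associated pathways (genes g1, g2) plus a third,
    gene-free pathway that only the healthy model can use; pyruvate feeds
    biomass directly and can spill into lactate secretion (g3) or
    respiration consuming oxygen and emitting ROS (g4). Consequences:

    - inhibiting g1 and g2 together collapses cancer biomass (>= 50%
      reduction) while each alone costs <= 10% and the healthy model,
      whose demand is covered by the gene-free pathway, loses <= 5%;
    - no other pair of genes achieves that contrast, so the planted pair
      is the unique genuine co-inhibition among all <= 2-gene groups;
    - the four labeled hallmark exchanges (Glu uptake, Lac secretion, O2
      uptake, ROS production) have different constrained maxima in the
      two models, so hallmark classification is non-degenerate.

    The rng only jitters the non-limiting sink capacities; the planted
    contrast is structural and holds for every seed.
    """
    rng = np.random.default_rng(rng_seed)
    big = float(rng.uniform(90.0, 110.0))  # non-limiting sink capacity

    def build(glc_ub: float, bypass_ub: float, o2_ub: float) -> MetabolicModel:
        reactions = [
            Reaction("EX_glc", {"glc": 1.0}, 0.0, glc_ub),                     # glucose uptake
            Reaction("PATH1", {"glc": -1.0, "pyr": 1.0}, 0.0, 9.5, gpr="g1"),
            Reaction("PATH2", {"glc": -1.0, "pyr": 1.0}, 0.0, 9.5, gpr="g2"),
            Reaction("PATH0", {"glc": -1.0, "pyr": 1.0}, 0.0, bypass_ub),      # gene-free bypass
            Reaction("BIOMASS", {"pyr": -1.0}, 0.0, 1000.0),
            Reaction("LDH", {"pyr": -1.0, "lac": 1.0}, 0.0, big, gpr="g3"),
            Reaction("EX_lac", {"lac": -1.0}, 0.0, big),                       # lactate secretion
            Reaction("EX_o2", {"o2": 1.0}, 0.0, o2_ub),                        # oxygen uptake
            Reaction("RESP", {"pyr": -1.0, "o2": -1.0, "ros": 1.0}, 0.0, big, gpr="g4"),
            Reaction("EX_ros", {"ros": -1.0}, 0.0, big),                       # ROS production
        ]
        return MetabolicModel(
            metabolites=["glc", "pyr", "lac", "o2", "ros"],
            reactions=reactions,
            genes=["g1", "g2", "g3", "g4"],
            biomass_rxn="BIOMASS",
            hallmark_rxns={"Glu": "EX_glc", "Lac": "EX_lac", "O2": "EX_o2", "ROS": "EX_ros"},
        )

    cancer = build(glc_ub=10.0, bypass_ub=0.0, o2_ub=2.0)    # glycolytic, hypoxic
    healthy = build(glc_ub=5.0, bypass_ub=5.0, o2_ub=10.0)   # lower demand, oxidative
    return cancer, healthy


PLANTED_GENE_PAIR = frozenset({"g1", "g2"})
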