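"""Selective multi-gene inhibition in paired cancer/healthy metabolic models.

Constraint-based (stoichiometric) models of a cancer cell line and a
healthy counterpart share the same reconstruction — identical metabolites,
reactions and gene-protein-reaction (GPR) rules — and differ only in flux
bounds. Gene inhibition is modeled at the reaction level: a reaction whose
GPR boolean expression (AND = complex subunits, OR = isozymes) evaluates
false once the inhibited genes are removed has both its bounds scaled to a
residual 1% of capacity (Vmax reduction). Growth is scored by flux balance
analysis (FBA) on the biomass reaction; metabolic cancer hallmarks
(glucose uptake, lactate secretion, oxygen consumption, ROS production)
are scored by flux variability analysis (FVA) of the hallmark exchange
maximal flux while maintaining 80% of the model's wild-type biomass.

A combined inhibition is *genuine polypharmacology* when it reduces cancer
biomass substantially more than any of its single-gene components while
leaving healthy biomass essentially intact. A hallmark call compares the
inhibited cancer maximal flux m_i against the cancer (m_c) and healthy
(m_h) wild-type values: movement of more than half the cancer-healthy gap
toward healthy is a strong reversal, movement away a worsening.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "Reaction",
    "MetabolicModel",
    "FluxResult",
    "fba",
    "fva",
    "apply_inhibition",
    "gpr_active",
    "InhibitionOutcome",
    "combo_screen",
    "HallmarkCall",
    "hallmark_classify",
]

RESIDUAL = 0.01          # fraction of Vmax left to an inhibited reaction
BIOMASS_FRACTION = 0.8   # biomass maintenance constraint during FVA


@dataclass
class Reaction:
    id: str
    stoich: dict  # metabolite -> coefficient (negative = consumed)
    lb: float
    ub: float
    gpr: str = ""  # boolean expression over genes; "" = no gene association

    def __post_init__(self) -> None:
        if self.lb > self.ub:
            raise ValueError(f"reaction {self.id}: lb {self.lb} > ub {self.ub}")


@dataclass
class MetabolicModel:
    """Stoichiometric model with bounds, GPR rules and labeled hallmarks."""

    metabolites: list[str]
    reactions: list[Reaction]
    genes: list[str]
    biomass_rxn: str
    hallmark_rxns: dict = field(default_factory=dict)  # label -> reaction id
    inhibited_genes: frozenset = frozenset()

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reaction ids")
        if self.biomass_rxn not in set(ids):
            raise ValueError(f"biomass reaction {self.biomass_rxn!r} not in model")
        declared = set(self.genes)
        for r in self.reactions:
            for g in _gpr_genes(r.gpr):
                if g not in declared:
                    raise ValueError(f"reaction {r.id}: GPR references undeclared gene {g!r}")

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(f"reaction {rxn_id!r} not in model")

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    def stoichiometric_matrix(self) -> np.ndarray:
        met_idx = {m: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, coef in r.stoich.items():
                S[met_idx[m], j] = coef
        return S

    # --- JSON round trip ---------------------------------------------------

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "metabolites": self.metabolites,
                    "reactions": [
                        {"id": r.id, "stoich": r.stoich, "lb": r.lb, "ub": r.ub, "gpr": r.gpr}
                        for r in self.reactions
                    ],
                    "genes": self.genes,
                    "biomass": self.biomass_rxn,
                    "hallmarks": self.hallmark_rxns,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "MetabolicModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            metabolites=d["metabolites"],
            reactions=[Reaction(**r) for r in d["reactions"]],
            genes=d["genes"],
            biomass_rxn=d["biomass"],
            hallmark_rxns=d.get("hallmarks", {}),
        )


# --- GPR evaluation --------------------------------------------------------

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def _gpr_genes(expr: str) -> set[str]:
    return {
        t for t in _TOKEN.findall(expr or "")
        if t not in {"(", ")"} and t.lower() not in {"and", "or"}
    }


def gpr_active(expr: str, inactive_genes: Iterable[str]) -> bool:
    """Evaluate a GPR boolean expression with the given genes knocked out.

    AND joins complex subunits (all required), OR joins isozymes (any
    suffices). An empty rule means no gene association: always active.
    """
    expr = (expr or "").strip()
    if not expr:
        return True
    inactive = set(inactive_genes)
    tokens = _TOKEN.findall(expr)

    def parse_or(pos: int) -> tuple[bool, int]:
        val, pos = parse_and(pos)
        while pos < len(tokens) and tokens[pos].lower() == "or":
            rhs, pos = parse_and(pos + 1)
            val = val or rhs
        return val, pos

    def parse_and(pos: int) -> tuple[bool, int]:
        val, pos = parse_atom(pos)
        while pos < len(tokens) and tokens[pos].lower() == "and":
            rhs, pos = parse_atom(pos + 1)
            val = val and rhs
        return val, pos

    def parse_atom(pos: int) -> tuple[bool, int]:
        if pos >= len(tokens):
            raise ValueError(f"truncated GPR expression: {expr!r}")
        tok = tokens[pos]
        if tok == "(":
            val, pos = parse_or(pos + 1)
            if pos >= len(tokens) or tokens[pos] != ")":
                raise ValueError(f"unbalanced parentheses in GPR: {expr!r}")
            return val, pos + 1
        if tok == ")" or tok.lower() in {"and", "or"}:
            raise ValueError(f"malformed GPR expression: {expr!r}")
        return tok not in inactive, pos + 1

    val, pos = parse_or(0)
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in GPR: {expr!r}")
    return val


# --- FBA / FVA -------------------------------------------------------------

@dataclass
class FluxResult:
    status: str  # "optimal" or "infeasible"
    objective: float | None
    fluxes: dict | None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def _solve(model: MetabolicModel, c: np.ndarray, extra_bounds: dict | None = None,
           maximize: bool = True) -> FluxResult:
    S = model.stoichiometric_matrix()
    bounds = []
    for r in model.reactions:
        lb, ub = r.lb, r.ub
        if extra_bounds and r.id in extra_bounds:
            lb, ub = extra_bounds[r.id]
        bounds.append((lb, ub))
    res = linprog(
        -c if maximize else c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
    )
    if not res.success:
        return FluxResult(status="infeasible", objective=None, fluxes=None)
    obj = float(-res.fun if maximize else res.fun)
    fluxes = {r.id: float(v) for r, v in zip(model.reactions, res.x)}
    return FluxResult(status="optimal", objective=obj, fluxes=fluxes)


def fba(model: MetabolicModel, objective: str | None = None) -> FluxResult:
    """Flux balance analysis: maximize the objective flux at steady state.

    Solves max c.v subject to S.v = 0 and the model bounds. Defaults to the
    biomass reaction. Infeasibility is reported in the result, not raised.
    """
    objective = objective or model.biomass_rxn
    c = np.zeros(len(model.reactions))
    ids = [r.id for r in model.reactions]
    if objective not in ids:
        raise KeyError(f"objective reaction {objective!r} not in model")
    c[ids.index(objective)] = 1.0
    return _solve(model, c, maximize=True)


def fva(
    model: MetabolicModel,
    reaction: str,
    biomass_fraction: float = BIOMASS_FRACTION,
) -> tuple[float, float] | FluxResult:
    """Flux range of a reaction while keeping a fraction of wild-type biomass.

    The model's own FBA optimum defines "wild-type"; the biomass flux is
    then constrained to at least ``biomass_fraction`` of it and the target
    reaction is minimized and maximized. Returns (min, max), or an
    infeasible :class:`FluxResult` when the fraction cannot be met.
    """
    ids = [r.id for r in model.reactions]
    if reaction not in ids:
        raise KeyError(f"reaction {reaction!r} not in model")
    wt = fba(model)
    if not wt.ok:
        return FluxResult(status="infeasible", objective=None, fluxes=None)
    bio = model.reaction(model.biomass_rxn)
    floor = biomass_fraction * wt.objective
    extra = {model.biomass_rxn: (min(floor, bio.ub), bio.ub)}
    c = np.zeros(len(model.reactions))
    c[ids.index(reaction)] = 1.0
    lo = _solve(model, c, extra_bounds=extra, maximize=False)
    hi = _solve(model, c, extra_bounds=extra, maximize=True)
    if not (lo.ok and hi.ok):
        return FluxResult(status="infeasible", objective=None, fluxes=None)
    return (lo.objective, hi.objective)


# --- inhibition ------------------------------------------------------------

def apply_inhibition(
    model: MetabolicModel, genes: Iterable[str], residual: float = RESIDUAL
) -> MetabolicModel:
    """Throttle reactions disabled by inhibiting the given genes.

    The GPR of every reaction is evaluated with the accumulated inhibited
    gene set removed; reactions that become inactive have both bounds
    multiplied by ``residual`` (reversible reactions are throttled in both
    directions). The input model is not modified, and re-applying the same
    gene set is a no-op (idempotent): bounds are scaled only for reactions
    newly inactivated relative to the model's recorded inhibition state.
    """
    genes = set(genes)
    unknown = genes - set(model.genes)
    if unknown:
        raise KeyError(f"unknown genes: {sorted(unknown)}")
    new_set = frozenset(model.inhibited_genes | genes)
    out = model.copy()
    out.inhibited_genes = new_set
    for r_old, r_new in zip(model.reactions, out.reactions):
        was_active = gpr_active(r_old.gpr, model.inhibited_genes)
        now_active = gpr_active(r_old.gpr, new_set)
        if was_active and not now_active:
            r_new.lb = r_old.lb * residual
            r_new.ub = r_old.ub * residual
    return out


# --- screening -------------------------------------------------------------

@dataclass
class HallmarkCall:
    call: str  # strong reversal | mild reversal | no effect | mild worsening | strong worsening
    ratio: float | None  # movement / (healthy - cancer) gap
    degenerate: bool = False
    infeasible: bool = False


def hallmark_classify(
    cancer_wt: MetabolicModel,
    cancer_inhibited: MetabolicModel,
    healthy_wt: MetabolicModel,
    hallmark: str,
    biomass_fraction: float = BIOMASS_FRACTION,
    eps: float = 0.05,
) -> HallmarkCall:
    """Classify the movement of a hallmark flux upon inhibition.

    Let m_c, m_i, m_h be the FVA maximal flux of the hallmark reaction (at
    the biomass maintenance fraction) in cancer wild-type, cancer
    inhibited and healthy wild-type. With gap d = m_h - m_c and movement
    m_i - m_c:

    - |movement| <= eps*|d|      -> no effect
    - movement/d > 0.5           -> strong reversal (approached healthy)
    - eps < movement/d <= 0.5    -> mild reversal
    - movement/d < -0.5          -> strong worsening (diverged)
    - otherwise (negative ratio) -> mild worsening

    A zero gap is degenerate and returns "no effect" flagged; an
    infeasible inhibited model is flagged as infeasible.
    """
    maxima = []
    for m in (cancer_wt, cancer_inhibited, healthy_wt):
        if hallmark not in {r.id for r in m.reactions}:
            raise KeyError(f"hallmark reaction {hallmark!r} not in model")
        rng = fva(m, hallmark, biomass_fraction)
        if isinstance(rng, FluxResult):
            return HallmarkCall(call="no effect", ratio=None, infeasible=True)
        maxima.append(rng[1])
    m_c, m_i, m_h = maxima
    d = m_h - m_c
    movement = m_i - m_c
    if d == 0:
        return HallmarkCall(call="no effect", ratio=None, degenerate=True)
    if abs(movement) <= eps * abs(d):
        return HallmarkCall(call="no effect", ratio=movement / d)
    ratio = movement / d
    if ratio > 0.5:
        return HallmarkCall(call="strong reversal", ratio=ratio)
    if ratio > 0:
        return HallmarkCall(call="mild reversal", ratio=ratio)
    if ratio < -0.5:
        return HallmarkCall(call="strong worsening", ratio=ratio)
    return HallmarkCall(call="mild worsening", ratio=ratio)


@dataclass
class InhibitionOutcome:
    genes: frozenset
    biomass_cancer_frac: float
    biomass_healthy_frac: float
    single_cancer_fracs: dict
    single_healthy_fracs: dict
    hallmark_calls: dict
    genuine_flag: bool

    @property
    def cancer_reduction(self) -> float:
        return 1.0 - self.biomass_cancer_frac

    @property
    def healthy_reduction(self) -> float:
        return 1.0 - self.biomass_healthy_frac

    @property
    def selectivity(self) -> float:
        return self.cancer_reduction - self.healthy_reduction


def combo_screen(
    cancer: MetabolicModel,
    healthy: MetabolicModel,
    candidate_groups: Sequence[Iterable[str]],
    residual: float = RESIDUAL,
    margin: float = 0.05,
    healthy_tol: float = 0.10,
    classify_hallmarks: bool = True,
) -> list[InhibitionOutcome]:
    """Screen candidate gene groups for selective combined inhibition.

    For each group, the combined inhibition and every single-gene
    inhibition are simulated on both models; biomass is reported as a
    fraction of the corresponding wild-type optimum. A group is flagged as
    genuine polypharmacology when the combined cancer biomass reduction
    exceeds the best single-gene reduction by more than ``margin`` (5
    percentage points by default) while the healthy reduction stays within
    ``healthy_tol``; singletons can never be genuine. Outcomes are sorted
    by cancer-vs-healthy selectivity, best first.
    """
    shared = set(cancer.genes) & set(healthy.genes)
    wt_c = fba(cancer)
    wt_h = fba(healthy)
    if not (wt_c.ok and wt_h.ok):
        raise RuntimeError(
            "wild-type FBA infeasible "
            f"(cancer: {wt_c.status}, healthy: {wt_h.status}); check model bounds"
        )
    outcomes = []
    for group in candidate_groups:
        genes = frozenset(group)
        if not genes <= shared:
            raise KeyError(f"genes not shared by both models: {sorted(genes - shared)}")

        def frac(model: MetabolicModel, wt: FluxResult, gset: Iterable[str]) -> float:
            res = fba(apply_inhibition(model, gset, residual))
            if not res.ok or wt.objective == 0:
                return 0.0
            return max(0.0, res.objective / wt.objective)

        combo_c = frac(cancer, wt_c, genes)
        combo_h = frac(healthy, wt_h, genes)
        singles_c = {g: frac(cancer, wt_c, {g}) for g in sorted(genes)}
        singles_h = {g: frac(healthy, wt_h, {g}) for g in sorted(genes)}
        best_single_red = max(1.0 - f for f in singles_c.values())
        genuine = (
            len(genes) >= 2
            and (1.0 - combo_c) > best_single_red + margin
            and (1.0 - combo_h) <= healthy_tol
        )
        calls = {}
        if classify_hallmarks and cancer.hallmark_rxns:
            inhibited = apply_inhibition(cancer, genes, residual)
            for label, rxn in cancer.hallmark_rxns.items():
                calls[label] = hallmark_classify(cancer, inhibited, healthy, rxn)
        outcomes.append(
            InhibitionOutcome(
                genes=genes,
                biomass_cancer_frac=combo_c,
                biomass_healthy_frac=combo_h,
                single_cancer_fracs=singles_c,
                single_healthy_fracs=singles_h,
                hallmark_calls=calls,
                genuine_flag=genuine,
            )
        )
    outcomes.sort(key=lambda o: (-o.selectivity, sorted(o.genes)))
    return outcomes
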