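"""Flux balance analysis of metabolic rewiring by gene loss.

Flux balance analysis (FBA) maximizes a biomass objective over the
steady-state flux cone {v : S v = 0, lb <= v <= ub} of a stoichiometric
model.  This module provides:

* :class:`MetabolicModel` — metabolites, bounded stoichiometric reactions,
  boolean gene-protein-reaction (GPR) rules, a biomass objective — with
  read/write support for SBML Level 3 (FBC) and a simple tabular dialect.
* :func:`fba_max_growth` — the LP itself (HiGHS via scipy.optimize).
* :func:`set_minimal_medium` — close all exchanges except a whitelist and
  open a single carbon source at a fixed uptake rate.
* :func:`gene_deletion_growth` — evaluate GPRs with a gene knocked out,
  zero the disabled reactions, and re-solve.
* :func:`flux_scan` — growth as a function of a fixed flux through one
  reaction (e.g. the glycine cleavage system or phosphoglucose isomerase).
* :func:`fva` — flux variability analysis at the growth optimum, flagging
  reactions whose flux must be (numerically) zero for maximum growth.
* :func:`must_be_off_genes` — the non-essential genes catalyzing those
  must-be-zero reactions, i.e. candidate adaptive loss-of-function targets.

Sign convention: exchange reactions are written ``met <=>`` (export
positive), so uptake is a negative exchange flux.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.sparse import lil_matrix

__all__ = [
    "Reaction",
    "MetabolicModel",
    "FluxSolution",
    "FVAResult",
    "MustOffReport",
    "parse_gpr",
    "eval_gpr",
    "gpr_genes",
    "read_model",
    "write_model",
    "set_minimal_medium",
    "fba_max_growth",
    "gene_deletion_growth",
    "gene_essentiality",
    "flux_scan",
    "fva",
    "must_be_off_genes",
]

SOLVER_TOL = 1e-9
DEFAULT_ZERO_TOL = 1e-6
_INF = 1000.0  # conventional "unbounded" flux bound


# ---------------------------------------------------------------------------
# GPR boolean expressions
# ---------------------------------------------------------------------------

_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(text: str):
    """Parse a boolean gene rule ("g1 and (g2 or g3)") into a nested AST.

    AST nodes: gene id string, or ("and", [..]) / ("or", [..]).  An empty
    rule parses to None (reaction not gene-associated).
    """
    tokens = _GPR_TOKEN.findall(text or "")
    if not tokens:
        return None
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        if pos >= len(tokens):
            raise ValueError(f"unexpected end of GPR {text!r}")
        tok = tokens[pos]
        pos += 1
        return tok

    def factor():
        tok = take()
        if tok == "(":
            node = expr()
            if peek() != ")":
                raise ValueError(f"unbalanced parentheses in GPR {text!r}")
            take()
            return node
        if tok in {")", "and", "or", "AND", "OR"}:
            raise ValueError(f"unexpected token {tok!r} in GPR {text!r}")
        return tok

    def term():
        parts = [factor()]
        while peek() is not None and peek().lower() == "and":
            take()
            parts.append(factor())
        return parts[0] if len(parts) == 1 else ("and", parts)

    def expr():
        parts = [term()]
        while peek() is not None and peek().lower() == "or":
            take()
            parts.append(term())
        return parts[0] if len(parts) == 1 else ("or", parts)

    node = expr()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in GPR {text!r}")
    return node


def eval_gpr(node, knocked_out: set[str]) -> bool:
    """True if the reaction remains catalyzed with the given genes removed.

    An empty rule (None) always evaluates True: spontaneous or orphan
    reactions survive any deletion.
    """
    if node is None:
        return True
    if isinstance(node, str):
        return node not in knocked_out
    op, parts = node
    if op == "and":
        return all(eval_gpr(p, knocked_out) for p in parts)
    return any(eval_gpr(p, knocked_out) for p in parts)


def gpr_genes(node) -> set[str]:
    if node is None:
        return set()
    if isinstance(node, str):
        return {node}
    _, parts = node
    out: set[str] = set()
    for p in parts:
        out |= gpr_genes(p)
    return out


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Mapping[str, float]  # metabolite -> coefficient (<0 consumed)
    lower_bound: float
    upper_bound: float
    gpr: str = ""
    objective: bool = False

    @property
    def is_exchange(self) -> bool:
        # single-metabolite boundary reaction; the biomass sink is not a medium exchange
        return len(self.stoichiometry) == 1 and not self.objective


@dataclass
class MetabolicModel:
    """A stoichiometric model with flux bounds, GPR rules, and an objective."""

    id: str
    metabolites: dict[str, str]  # id -> compartment
    reactions: list[Reaction]
    genes: list[str] = field(default_factory=list)
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        declared = set(self.genes)
        inferred: set[str] = set()
        n_obj = 0
        for rxn in self.reactions:
            if rxn.id in seen:
                raise ValueError(f"duplicate reaction id {rxn.id!r}")
            seen.add(rxn.id)
            if rxn.lower_bound > rxn.upper_bound:
                raise ValueError(f"reaction {rxn.id!r}: lb > ub")
            for met in rxn.stoichiometry:
                if met not in self.metabolites:
                    raise ValueError(
                        f"reaction {rxn.id!r} references unknown metabolite {met!r}"
                    )
            inferred |= gpr_genes(parse_gpr(rxn.gpr))
            n_obj += bool(rxn.objective)
        if n_obj == 0:
            raise ValueError("model has no objective reaction")
        if declared and not inferred <= declared:
            raise ValueError(
                f"GPR references undeclared genes: {sorted(inferred - declared)}"
            )
        if not declared:
            self.genes = sorted(inferred)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def objective_id(self) -> str:
        return next(r.id for r in self.reactions if r.objective)

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def with_bounds(self, bounds: Mapping[str, tuple[float, float]]) -> "MetabolicModel":
        """Copy of the model with selected reaction bounds replaced."""
        new = [
            replace(r, lower_bound=bounds[r.id][0], upper_bound=bounds[r.id][1])
            if r.id in bounds
            else r
            for r in self.reactions
        ]
        return MetabolicModel(self.id, dict(self.metabolites), new, list(self.genes), dict(self.notes))

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str]]:
        mets = sorted(self.metabolites)
        midx = {m: i for i, m in enumerate(mets)}
        S = lil_matrix((len(mets), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                S[midx[met], j] = coef
        return S.tocsr(), mets


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded | failed
    objective_value: float
    fluxes: pd.Series

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class FVAResult:
    """Per-reaction attainable flux ranges at (near-)maximal growth."""

    ranges: pd.DataFrame  # columns: min, max, zero_required
    optimum: float
    opt_tol: float
    zero_tol: float

    @property
    def zero_required(self) -> list[str]:
        return list(self.ranges.index[self.ranges["zero_required"]])


@dataclass
class MustOffReport:
    zero_required_reactions: list[str]
    implicated_genes: list[str]
    essential_excluded: list[str]
    final_genes: list[str]

    @property
    def final_count(self) -> int:
        return len(self.final_genes)


# ---------------------------------------------------------------------------
# tabular dialect I/O
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "-->")


def _parse_side(side: str) -> dict[str, float]:
    out: dict[str, float] = {}
    side = side.strip()
    if not side:
        return out
    for term in side.split("+"):
        parts = term.split()
        if len(parts) == 1:
            met, coef = parts[0], 1.0
        elif len(parts) == 2:
            coef, met = float(parts[0]), parts[1]
        else:
            raise ValueError(f"cannot parse stoichiometric term {term!r}")
        out[met] = out.get(met, 0.0) + float(coef)
    return out


def parse_equation(eq: str) -> tuple[dict[str, float], bool]:
    """Parse 'a + 2 b --> c' / 'a <=> b'. Returns (stoichiometry, reversible)."""
    for arrow in _ARROWS:
        if arrow in eq:
            left, right = eq.split(arrow)
            stoich: dict[str, float] = {}
            for met, coef in _parse_side(left).items():
                stoich[met] = stoich.get(met, 0.0) - coef
            for met, coef in _parse_side(right).items():
                stoich[met] = stoich.get(met, 0.0) + coef
            stoich = {m: c for m, c in stoich.items() if c != 0}
            if not stoich:
                raise ValueError(f"equation {eq!r} has empty net stoichiometry")
            return stoich, arrow == "<=>"
    raise ValueError(f"equation {eq!r} lacks an arrow (--> or <=>)")


def format_equation(rxn: Reaction) -> str:
    def fmt(items):
        return " + ".join(
            met if coef == 1 else f"{coef:g} {met}"
            for met, coef in sorted(items)
        )

    left = [(m, -c) for m, c in rxn.stoichiometry.items() if c < 0]
    right = [(m, c) for m, c in rxn.stoichiometry.items() if c > 0]
    arrow = "<=>" if rxn.lower_bound < 0 else "-->"
    return f"{fmt(left)} {arrow} {fmt(right)}".strip()


def _compartment_of(met: str) -> str:
    return "e" if met.endswith("_e") else "c"


def _read_table(path: Path) -> MetabolicModel:
    df = pd.read_csv(path, sep="\t", comment="#").fillna({"gpr": ""})
    required = {"id", "equation", "lb", "ub", "gpr", "objective"}
    if not required <= set(df.columns):
        raise ValueError(f"table model needs columns {sorted(required)}")
    reactions = []
    metabolites: dict[str, str] = {}
    for row in df.itertuples(index=False):
        try:
            stoich, _ = parse_equation(row.equation)
        except ValueError as exc:
            raise ValueError(f"reaction {row.id!r}: {exc}") from exc
        for met in stoich:
            metabolites.setdefault(met, _compartment_of(met))
        reactions.append(
            Reaction(
                id=str(row.id),
                stoichiometry=stoich,
                lower_bound=float(row.lb),
                upper_bound=float(row.ub),
                gpr=str(row.gpr) if row.gpr else "",
                objective=bool(int(row.objective)),
            )
        )
    return MetabolicModel(id=path.stem, metabolites=metabolites, reactions=reactions)


def _write_table(model: MetabolicModel, path: Path) -> None:
    rows = [
        {
            "id": r.id,
            "equation": format_equation(r),
            "lb": r.lower_bound,
            "ub": r.upper_bound,
            "gpr": r.gpr,
            "objective": int(r.objective),
        }
        for r in model.reactions
    ]
    with open(path, "w") as fh:
        fh.write("# lofadapt tabular metabolic model; uptake = negative exchange flux\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SBML Level 3 (FBC) I/O
# ---------------------------------------------------------------------------

def _read_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromString(Path(path).read_text())
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ValueError(f"SBML parse error: {doc.getError(0).getMessage()}")
    sm = doc.getModel()
    if sm is None:
        raise ValueError("SBML document contains no model")
    mets = {s.getId(): (s.getCompartment() or "c") for s in sm.getListOfSpecies()}
    fbc = sm.getPlugin("fbc")
    obj_id = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        if obj.getNumFluxObjectives() > 0:
            obj_id = obj.getFluxObjective(0).getReaction()

    def bound_value(param_id, default):
        p = sm.getParameter(param_id) if param_id else None
        return p.getValue() if p is not None else default

    reactions = []
    for rx in sm.getListOfReactions():
        stoich: dict[str, float] = {}
        for i in range(rx.getNumReactants()):
            sr = rx.getReactant(i)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for i in range(rx.getNumProducts()):
            sr = rx.getProduct(i)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        rfbc = rx.getPlugin("fbc")
        if rfbc is not None and rfbc.isSetLowerFluxBound():
            lb = bound_value(rfbc.getLowerFluxBound(), -_INF)
            ub = bound_value(rfbc.getUpperFluxBound(), _INF)
        else:
            lb = -_INF if rx.getReversible() else 0.0
            ub = _INF
        gpr = ""
        if rfbc is not None and rfbc.isSetGeneProductAssociation():
            gpr = _gpa_to_text(rfbc.getGeneProductAssociation().getAssociation(), sm)
        reactions.append(
            Reaction(
                id=rx.getId(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                objective=(rx.getId() == obj_id),
            )
        )
    return MetabolicModel(id=sm.getId() or path.stem, metabolites=mets, reactions=reactions)


def _gpa_to_text(assoc, sm) -> str:
    import libsbml

    if assoc is None:
        return ""
    if isinstance(assoc, libsbml.GeneProductRef):
        gp = sm.getPlugin("fbc").getGeneProduct(assoc.getGeneProduct())
        return gp.getLabel() or gp.getId()
    parts = [
        _gpa_to_text(assoc.getAssociation(i), sm)
        for i in range(assoc.getNumAssociations())
    ]
    op = " and " if isinstance(assoc, libsbml.FbcAnd) else " or "
    return "(" + op.join(parts) + ")"


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(re.sub(r"\W", "_", model.id))
    mfbc = sm.getPlugin("fbc")
    mfbc.setStrict(True)

    for comp in sorted(set(model.metabolites.values())):
        c = sm.createCompartment()
        c.setId(comp)
        c.setConstant(True)
    for met, comp in sorted(model.metabolites.items()):
        s = sm.createSpecies()
        s.setId(met)
        s.setCompartment(comp)
        s.setConstant(False)
        s.setBoundaryCondition(False)
        s.setHasOnlySubstanceUnits(False)
    for g in model.genes:
        gp = mfbc.createGeneProduct()
        gp.setId(f"G_{re.sub(r'[^A-Za-z0-9_]', '_', g)}")
        gp.setLabel(g)

    def param_for(value: float) -> str:
        pid = "p_" + re.sub(r"[^A-Za-z0-9]", "_", f"{value:g}")
        if sm.getParameter(pid) is None:
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
        return pid

    gid = {g: f"G_{re.sub(r'[^A-Za-z0-9_]', '_', g)}" for g in model.genes}
    for rxn in model.reactions:
        rx = sm.createReaction()
        rx.setId(rxn.id)
        rx.setReversible(rxn.lower_bound < 0)
        rx.setFast(False)
        for met, coef in rxn.stoichiometry.items():
            sr = rx.createReactant() if coef < 0 else rx.createProduct()
            sr.setSpecies(met)
            sr.setStoichiometry(abs(coef))
            sr.setConstant(True)
        rfbc = rx.getPlugin("fbc")
        rfbc.setLowerFluxBound(param_for(rxn.lower_bound))
        rfbc.setUpperFluxBound(param_for(rxn.upper_bound))
        ast = parse_gpr(rxn.gpr)
        if ast is not None:
            gpa = rfbc.createGeneProductAssociation()
            _build_gpa(gpa, ast, gid)

    obj = mfbc.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fo = obj.createFluxObjective()
    fo.setReaction(model.objective_id)
    fo.setCoefficient(1.0)
    mfbc.setActiveObjectiveId("obj")
    Path(path).write_text(libsbml.writeSBMLToString(doc))


def _build_gpa(parent, node, gid: Mapping[str, str]) -> None:
    if isinstance(node, str):
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(gid[node])
        return
    op, parts = node
    holder = parent.createAnd() if op == "and" else parent.createOr()
    for p in parts:
        _build_gpa(holder, p, gid)


def read_model(path: str | Path, dialect: str = "table") -> MetabolicModel:
    """Read a metabolic model ('table' dialect or 'sbml' Level 3 + FBC)."""
    path = Path(path)
    if dialect == "table":
        return _read_table(path)
    if dialect == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_model(model: MetabolicModel, path: str | Path, dialect: str = "table") -> None:
    path = Path(path)
    if dialect == "table":
        _write_table(model, path)
    elif dialect == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# medium setup
# ---------------------------------------------------------------------------

def set_minimal_medium(
    model: MetabolicModel,
    carbon_exchange: str,
    uptake: float = 10.0,
    keep_open: Iterable[str] = (),
) -> MetabolicModel:
    """Minimal medium: close every exchange's uptake except a whitelist of
    freely available (inorganic/mineral) exchanges, and allow uptake of the
    sole carbon source at the given rate (mmol gDW^-1 h^-1).

    Uptake is flux *into* the cell, i.e. exchange lower bound -uptake.
    """
    rxn = model.reaction(carbon_exchange)
    if not rxn.is_exchange:
        raise ValueError(f"{carbon_exchange!r} is not an exchange reaction")
    if uptake < 0:
        raise ValueError("uptake must be non-negative")
    whitelist = set(keep_open)
    bounds: dict[str, tuple[float, float]] = {}
    for ex in model.exchanges:
        if ex.id == carbon_exchange:
            bounds[ex.id] = (-uptake, ex.upper_bound)
        elif ex.id not in whitelist:
            bounds[ex.id] = (max(ex.lower_bound, 0.0), ex.upper_bound)
    return model.with_bounds(bounds)


# ---------------------------------------------------------------------------
# linear programming core
# ---------------------------------------------------------------------------

_STATUS = {0: "optimal", 1: "failed", 2: "infeasible", 3: "unbounded", 4: "failed"}


def _solve(model: MetabolicModel, c: np.ndarray, extra_ub=None) -> tuple[str, float, np.ndarray]:
    """Minimize c.v over {S v = 0, bounds} (+ optional A_ub v <= b_ub rows)."""
    S, _ = model.stoichiometric_matrix()
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    A_ub = b_ub = None
    if extra_ub is not None:
        A_ub, b_ub = extra_ub
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
    )
    status = _STATUS.get(res.status, "failed")
    x = res.x if res.x is not None else np.full(len(model.reactions), np.nan)
    val = float(res.fun) if res.fun is not None else np.nan
    return status, val, x


def fba_max_growth(model: MetabolicModel) -> FluxSolution:
    """Maximize the biomass objective; returns status, growth rate, fluxes."""
    c = np.zeros(len(model.reactions))
    c[model.reaction_ids.index(model.objective_id)] = -1.0
    status, val, x = _solve(model, c)
    obj = -val if status == "optimal" else np.nan
    return FluxSolution(
        status=status,
        objective_value=obj,
        fluxes=pd.Series(x, index=model.reaction_ids, name="flux"),
    )


def gene_deletion_growth(
    model: MetabolicModel, gene: str, tol: float = 1e-6
) -> tuple[float, bool]:
    """Growth after knocking out one gene; flags essentiality for maximum
    growth (relative growth loss > tol)."""
    if gene not in model.genes:
        raise ValueError(f"unknown gene {gene!r}")
    full = fba_max_growth(model)
    if not full.ok:
        raise ValueError(f"base model not solvable: {full.status}")
    knocked = {gene}
    bounds = {
        r.id: (0.0, 0.0)
        for r in model.reactions
        if r.gpr and not eval_gpr(parse_gpr(r.gpr), knocked)
    }
    if not bounds:
        return full.objective_value, False
    sol = fba_max_growth(model.with_bounds(bounds))
    growth = sol.objective_value if sol.ok else 0.0
    if full.objective_value <= tol:
        return growth, False
    essential = (full.objective_value - growth) > tol * full.objective_value
    return growth, essential


def gene_essentiality(model: MetabolicModel, tol: float = 1e-6) -> dict[str, bool]:
    """Essential-for-maximum-growth flag for every declared gene."""
    return {g: gene_deletion_growth(model, g, tol)[1] for g in model.genes}


def flux_scan(
    model: MetabolicModel, reaction: str, values: Sequence[float]
) -> pd.DataFrame:
    """Maximum growth with one reaction's flux pinned to each given value.

    Infeasible points are reported with status 'infeasible' and NaN growth.
    """
    model.reaction(reaction)  # existence check
    rows = []
    for v in values:
        sol = fba_max_growth(model.with_bounds({reaction: (float(v), float(v))}))
        rows.append((float(v), sol.objective_value if sol.ok else np.nan, sol.status))
    return pd.DataFrame(rows, columns=["flux", "growth", "status"]).set_index("flux")


def fva(
    model: MetabolicModel,
    opt_tol: float = 0.0,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> FVAResult:
    """Flux variability analysis with the objective held at (1-opt_tol) of
    its optimum; flags reactions whose flux range is confined to
    [-zero_tol, zero_tol] (must be off for maximum growth)."""
    base = fba_max_growth(model)
    if not base.ok:
        raise ValueError(f"cannot run FVA: base FBA status {base.status}")
    opt = base.objective_value
    n = len(model.reactions)
    obj_idx = model.reaction_ids.index(model.objective_id)
    row = np.zeros((1, n))
    row[0, obj_idx] = -1.0  # -v_obj <= -(1-opt_tol)*opt
    extra = (row, np.array([-(1.0 - opt_tol) * opt + SOLVER_TOL]))

    mins = np.empty(n)
    maxs = np.empty(n)
    for j in range(n):
        c = np.zeros(n)
        c[j] = 1.0
        status, val, _ = _solve(model, c, extra_ub=extra)
        mins[j] = val if status == "optimal" else np.nan
        c[j] = -1.0
        status, val, _ = _solve(model, c, extra_ub=extra)
        maxs[j] = -val if status == "optimal" else np.nan
    ranges = pd.DataFrame(
        {
            "min": mins,
            "max": maxs,
            "zero_required": (np.abs(mins) <= zero_tol) & (np.abs(maxs) <= zero_tol),
        },
        index=model.reaction_ids,
    )
    return FVAResult(ranges=ranges, optimum=opt, opt_tol=opt_tol, zero_tol=zero_tol)


def must_be_off_genes(
    model: MetabolicModel,
    fva_result: FVAResult,
    essential_flags: Mapping[str, bool],
) -> MustOffReport:
    """Genes catalyzing (alone or in complexes/isozymes) reactions that must
    carry zero flux at maximum growth, minus growth-essential genes."""
    zero_rxns = fva_result.zero_required
    implicated: set[str] = set()
    for rid in zero_rxns:
        implicated |= gpr_genes(parse_gpr(model.reaction(rid).gpr))
    essential = {g for g in implicated if essential_flags.get(g, False)}
    final = sorted(implicated - essential)
    return MustOffReport(
        zero_required_reactions=zero_rxns,
        implicated_genes=sorted(implicated),
        essential_excluded=sorted(essential),
        final_genes=final,
    )
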