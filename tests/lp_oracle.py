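"""Independent brute-force oracle for small flux polytopes.

Enumerates all basic feasible solutions (vertices) of
{v : S v = 0, lb <= v <= ub} by fixing every choice of n - rank(S)
variables at a bound and solving the remaining square-ish system.  Only
meant for toy models (<= ~10 reactions); used to cross-check the LP-based
FBA/FVA implementation without going through any LP solver.
"""

from __future__ import annotations

import itertools

import numpy as np

TOL = 1e-7


def enumerate_vertices(model) -> np.ndarray:
    S, _ = model.stoichiometric_matrix()
    S = S.toarray()
    n = len(model.reactions)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    rank = np.linalg.matrix_rank(S)
    k = n - rank
    verts = []
    for nonbasic in itertools.combinations(range(n), k):
        basic = [j for j in range(n) if j not in nonbasic]
        B = S[:, basic]
        for sides in itertools.product((0, 1), repeat=k):
            v = np.zeros(n)
            for j, side in zip(nonbasic, sides):
                v[j] = lb[j] if side == 0 else ub[j]
            rhs = -S[:, list(nonbasic)] @ v[list(nonbasic)]
            sol, *_ = np.linalg.lstsq(B, rhs, rcond=None)
            v[basic] = sol
            if np.max(np.abs(S @ v)) > TOL:
                continue
            if np.any(v < lb - TOL) or np.any(v > ub + TOL):
                continue
            verts.append(np.clip(v, lb, ub))
    verts = np.array(verts)
    # deduplicate
    out = []
    for v in verts:
        if not any(np.allclose(v, w, atol=1e-6) for w in out):
            out.append(v)
    return np.array(out)


def oracle_max_growth(model) -> tuple[float, np.ndarray]:
    verts = enumerate_vertices(model)
    obj = model.reaction_ids.index(model.objective_id)
    best = np.argmax(verts[:, obj])
    return float(verts[best, obj]), verts


def oracle_flux_ranges(model, opt_tol: float = 0.0) -> tuple[float, np.ndarray, np.ndarray]:
    """Per-reaction min/max flux over the optimal face, via the vertices of
    the polytope restricted to (near-)optimal objective value."""
    opt, verts = oracle_max_growth(model)
    obj = model.reaction_ids.index(model.objective_id)
    optimal = verts[verts[:, obj] >= (1.0 - opt_tol) * opt - 1e-9]
    return opt, optimal.min(axis=0), optimal.max(axis=0)


def oracle_zero_required(model, zero_tol: float = 1e-6) -> list[str]:
    _, mins, maxs = oracle_flux_ranges(model)
    return [
        rid
        for rid, lo, hi in zip(model.reaction_ids, mins, maxs)
        if abs(lo) <= zero_tol and abs(hi) <= zero_tol
    ]


def oracle_max_growth_at_flux(model, reaction: str, value: float) -> float:
    """Optimum with one reaction pinned; NaN if infeasible."""
    pinned = model.with_bounds({reaction: (value, value)})
    verts = enumerate_vertices(pinned)
    if verts.size == 0:
        return float("nan")
    obj = model.reaction_ids.index(model.objective_id)
    return float(verts[:, obj].max())
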