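"""Independent brute-force oracles used only by the tests.

The FVA oracle enumerates the vertices of the optimal-flux polytope
{S·v = 0, ratio equalities, c·v = opt, lb <= v <= ub} by solving the
equality system with every choice of pinned bounds, then reads each
reaction's min/max off the vertex set.  It shares no code with the
LP-based implementation it checks.  Only viable for tiny models
(<= ~8 reactions).
"""

from __future__ import annotations

import itertools

import numpy as np

from fluxcord.model import StoichiometricModel


def enumerate_vertices(
    A_eq: np.ndarray,
    b_eq: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    tol: float = 1e-9,
) -> np.ndarray:
    """All vertices of {A_eq v = b_eq, lb <= v <= ub} by basis enumeration."""
    n = A_eq.shape[1]
    rank = np.linalg.matrix_rank(A_eq, tol=1e-10)
    n_pin = n - rank
    vertices = []
    for idx in itertools.combinations(range(n), n_pin):
        for vals in itertools.product(*[(lb[j], ub[j]) for j in idx]):
            rows = np.zeros((n_pin, n))
            rhs = np.zeros(n_pin)
            for r, (j, val) in enumerate(zip(idx, vals)):
                rows[r, j] = 1.0
                rhs[r] = val
            A = np.vstack([A_eq, rows])
            b = np.concatenate([b_eq, rhs])
            v, *_ = np.linalg.lstsq(A, b, rcond=None)
            if np.max(np.abs(A @ v - b)) > 1e-7:
                continue
            if np.all(v >= lb - 1e-7) and np.all(v <= ub + 1e-7):
                vertices.append(np.clip(v, lb, ub))
    if not vertices:
        raise ValueError("no feasible vertex found")
    return np.array(vertices)


def fva_oracle(
    model: StoichiometricModel,
    optimum: float,
) -> dict[str, tuple[float, float]]:
    """Per-reaction [vmin, vmax] of the optimal flux space by vertex
    enumeration (optimum must come from an independent computation or a
    hand solution)."""
    S = model.stoichiometric_matrix()
    n = len(model.reactions)
    rxn_index = {r.id: j for j, r in enumerate(model.reactions)}
    rows = [S]
    for fr in model.flux_ratios:
        row = np.zeros((1, n))
        row[0, rxn_index[fr.numerator]] = 1.0
        row[0, rxn_index[fr.denominator]] = -fr.ratio
        rows.append(row)
    obj = np.zeros((1, n))
    obj[0, rxn_index[model.objective]] = 1.0
    rows.append(obj)
    A_eq = np.vstack(rows)
    b_eq = np.zeros(A_eq.shape[0])
    b_eq[-1] = optimum
    lb, ub = model.bounds()
    verts = enumerate_vertices(A_eq, b_eq, lb, ub)
    return {
        rid: (float(verts[:, j].min()), float(verts[:, j].max()))
        for rid, j in rxn_index.items()
    }
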