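"""Flux balance analysis, flux variability analysis, and T/S/N calls.

FBA maximizes the objective flux subject to steady-state mass balance
(S·v = 0), reaction bounds, and any flux-ratio equalities.  FVA then
minimizes and maximizes each reaction flux with the objective pinned to
(a fraction of) its optimum, yielding per-reaction intervals
[vmin, vmax] that confine the feasible optimal flux space.

Responsiveness classification compares the interval bounds of two
accessions by flux *magnitude*: a bound is called "T" when its absolute
value is larger in the high-lipid (TAG-accumulating) accession A, "S"
when larger in the high-starch accession B, and "N" when the difference
is within the numerical tolerance (default 1e-7 μmol/h).  The combined
per-reaction call ignores N bounds and flags mixed T/S bounds as "X"
(ambiguous, excluded from concordance counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from fluxcord.model import FluxRatioConstraint, StoichiometricModel

#: default tolerance below which a flux-magnitude difference is noise
EPSILON = 1e-7
#: LP feasibility tolerance; fluxes below it are snapped to zero
LP_TOL = 1e-9


class InfeasibleModelError(RuntimeError):
    pass


class UnboundedModelError(RuntimeError):
    pass


@dataclass
class FBAResult:
    objective_value: float
    fluxes: pd.Series  # indexed by reaction id


@dataclass
class FluxBoundsSet:
    """Per-reaction FVA intervals for one accession."""

    accession: str
    bounds: pd.DataFrame  # index: reaction id; columns: vmin, vmax

    def __post_init__(self):
        self.bounds.index.name = "reaction_id"
        bad = self.bounds[self.bounds["vmin"] > self.bounds["vmax"] + 1e-6]
        if len(bad):
            raise ValueError(
                f"vmin > vmax for reactions {list(bad.index)} "
                f"(accession {self.accession})"
            )

    def to_tsv(self, path: str | Path) -> None:
        df = self.bounds.copy()
        df.insert(0, "accession", self.accession)
        df.to_csv(path, sep="\t", index_label="reaction_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FluxBoundsSet":
        df = pd.read_csv(path, sep="\t", index_col="reaction_id", comment="#")
        acc = df["accession"].iloc[0]
        return cls(accession=str(acc), bounds=df[["vmin", "vmax"]])


@dataclass(frozen=True)
class ResponsivenessCall:
    """T/S/N call per FVA bound plus the combined per-reaction call."""

    reaction_id: str
    lower_call: str
    upper_call: str
    combined: str
    tolerance: float = EPSILON


def _lp_arrays(
    model: StoichiometricModel,
    ratio_constraints: list[FluxRatioConstraint] | None,
):
    S = model.stoichiometric_matrix()
    n = len(model.reactions)
    rxn_index = {r.id: j for j, r in enumerate(model.reactions)}
    rows = [S]
    ratios = model.flux_ratios if ratio_constraints is None else ratio_constraints
    for fr in ratios:
        row = np.zeros((1, n))
        row[0, rxn_index[fr.numerator]] = 1.0
        row[0, rxn_index[fr.denominator]] = -fr.ratio
        rows.append(row)
    A_eq = np.vstack(rows)
    b_eq = np.zeros(A_eq.shape[0])
    lb, ub = model.bounds()
    return A_eq, b_eq, lb, ub, rxn_index


def _solve(c, A_eq, b_eq, A_ub, b_ub, lb, ub, what: str):
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleModelError(f"{what}: LP infeasible")
    if res.status == 3:
        raise UnboundedModelError(f"{what}: LP unbounded")
    if res.status != 0:  # pragma: no cover
        raise RuntimeError(f"{what}: solver failure ({res.message})")
    return res


def fba(
    model: StoichiometricModel,
    ratio_constraints: list[FluxRatioConstraint] | None = None,
) -> FBAResult:
    """Maximize the model objective; return the optimum and one flux vector.

    ``ratio_constraints`` overrides the model's own flux ratios when
    given (pass ``[]`` to drop them).
    """
    A_eq, b_eq, lb, ub, rxn_index = _lp_arrays(model, ratio_constraints)
    c = np.zeros(len(model.reactions))
    c[rxn_index[model.objective]] = -1.0  # linprog minimizes
    res = _solve(c, A_eq, b_eq, None, None, lb, ub, f"FBA({model.id})")
    v = np.where(np.abs(res.x) < LP_TOL, 0.0, res.x)
    return FBAResult(
        objective_value=float(-res.fun),
        fluxes=pd.Series(v, index=model.reaction_ids),
    )


def fva(
    model: StoichiometricModel,
    ratio_constraints: list[FluxRatioConstraint] | None = None,
    optimality_fraction: float = 1.0,
    accession: str = "",
) -> FluxBoundsSet:
    """Flux variability analysis at (a fraction of) the FBA optimum.

    For every reaction the flux is minimized and maximized subject to
    mass balance, bounds, ratio equalities and
    ``v_objective >= optimality_fraction * optimum``.
    """
    if not 0.0 <= optimality_fraction <= 1.0:
        raise ValueError("optimality_fraction must be in [0, 1]")
    opt = fba(model, ratio_constraints).objective_value
    A_eq, b_eq, lb, ub, rxn_index = _lp_arrays(model, ratio_constraints)
    n = len(model.reactions)
    # objective >= f * opt  as  -v_obj <= -f * opt
    A_ub = np.zeros((1, n))
    A_ub[0, rxn_index[model.objective]] = -1.0
    # back off by the solver tolerance so the optimal face stays feasible
    b_ub = np.array([-(optimality_fraction * opt) + LP_TOL])

    vmin = np.empty(n)
    vmax = np.empty(n)
    for j, rid in enumerate(model.reaction_ids):
        c = np.zeros(n)
        c[j] = 1.0
        try:
            vmin[j] = _solve(c, A_eq, b_eq, A_ub, b_ub, lb, ub, f"FVA min {rid}").fun
            vmax[j] = -_solve(-c, A_eq, b_eq, A_ub, b_ub, lb, ub, f"FVA max {rid}").fun
        except (InfeasibleModelError, UnboundedModelError) as exc:
            raise type(exc)(f"reaction {rid!r}: {exc}") from exc
    vmin = np.where(np.abs(vmin) < LP_TOL, 0.0, vmin)
    vmax = np.where(np.abs(vmax) < LP_TOL, 0.0, vmax)
    # FVA min/max of the same LP can cross by solver tolerance only
    vmin = np.minimum(vmin, vmax)
    return FluxBoundsSet(
        accession=accession,
        bounds=pd.DataFrame(
            {"vmin": vmin, "vmax": vmax}, index=pd.Index(model.reaction_ids)
        ),
    )


def _bound_call(bA: float, bB: float, eps: float) -> str:
    a, b = abs(bA), abs(bB)
    if a > b + eps:
        return "T"
    if b > a + eps:
        return "S"
    return "N"


def combine_bound_calls(lower: str, upper: str) -> str:
    """Combined per-reaction call: ignore N; mixed T/S is ambiguous (X)."""
    calls = {lower, upper} - {"N"}
    if not calls:
        return "N"
    if calls == {"T"}:
        return "T"
    if calls == {"S"}:
        return "S"
    return "X"


def classify_responsiveness(
    bounds_a: FluxBoundsSet,
    bounds_b: FluxBoundsSet,
    eps: float = EPSILON,
) -> list[ResponsivenessCall]:
    """Call each reaction T/S/N per FVA bound and combine.

    Accession A is the designated high-lipid variant: "T" means the flux
    magnitude of a bound is larger in A by more than ``eps``, "S" larger
    in B.  Fluxes below the LP tolerance are snapped to zero first.
    """
    ra, rb = set(bounds_a.bounds.index), set(bounds_b.bounds.index)
    if ra != rb:
        raise ValueError(
            f"reaction sets differ: only in A {sorted(ra - rb)[:5]}, "
            f"only in B {sorted(rb - ra)[:5]}"
        )
    calls = []
    for rid in bounds_a.bounds.index:
        a = bounds_a.bounds.loc[rid]
        b = bounds_b.bounds.loc[rid]
        snap = lambda x: 0.0 if abs(x) < LP_TOL else float(x)
        lo = _bound_call(snap(a["vmin"]), snap(b["vmin"]), eps)
        hi = _bound_call(snap(a["vmax"]), snap(b["vmax"]), eps)
        calls.append(
            ResponsivenessCall(
                reaction_id=str(rid),
                lower_call=lo,
                upper_call=hi,
                combined=combine_bound_calls(lo, hi),
                tolerance=eps,
            )
        )
    return calls


def responsiveness_frame(calls: list[ResponsivenessCall]) -> pd.DataFrame:
    """Tabulate calls: index reaction_id; columns lower/upper/combined."""
    return pd.DataFrame(
        {
            "lower_call": [c.lower_call for c in calls],
            "upper_call": [c.upper_call for c in calls],
            "combined": [c.combined for c in calls],
        },
        index=pd.Index([c.reaction_id for c in calls], name="reaction_id"),
    )
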