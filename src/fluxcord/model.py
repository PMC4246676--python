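"""Stoichiometric model container and I/O.

A :class:`StoichiometricModel` holds metabolites (with compartments),
reactions (stoichiometry, flux bounds, gene associations, pathway and
compartment labels) and a single objective reaction.  Flux-ratio
constraints — fixed ratios between two fluxes, encoded as homogeneous
linear equalities ``v_num - r * v_den = 0`` — carry externally measured
flux information into the model.

Models are stored as JSON (schema below); a subset of SBML Level-3 core
with the FBC extension can be imported when python-libsbml is available.

JSON schema::

    {
      "id": "<model id>",
      "metabolites": [{"id", "name", "compartment"}, ...],
      "reactions": [{"id", "name", "stoichiometry": {met: coeff},
                     "lower_bound", "upper_bound", "pathway",
                     "compartment", "genes": [...], "exchange": bool}, ...],
      "objective": "<reaction id>",
      "flux_ratios": [{"numerator", "denominator", "ratio"}, ...]
    }

Stoichiometric coefficients are negative for consumed metabolites.
Flux units are μmol h⁻¹ throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class ModelValidationError(ValueError):
    """Raised when a model violates its structural invariants.

    ``violations`` lists every problem found, not just the first.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "invalid model:\n" + "\n".join(f"  - {v}" for v in violations)
        )


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass
class Reaction:
    """A biochemical or transport reaction.

    ``genes`` carries the associated gene identifiers with
    any-gene-suffices semantics (no AND/OR structure); ``exchange``
    marks boundary reactions whose stoichiometry may be one-sided.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    name: str = ""
    pathway: str = ""
    compartment: str = ""
    genes: list[str] = field(default_factory=list)
    exchange: bool = False


@dataclass(frozen=True)
class FluxRatioConstraint:
    """v_numerator = ratio * v_denominator, as a linear equality."""

    numerator: str
    denominator: str
    ratio: float


@dataclass
class StoichiometricModel:
    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective: str
    flux_ratios: list[FluxRatioConstraint] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    # -- lookups ---------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        try:
            return next(r for r in self.reactions if r.id == rid)
        except StopIteration:
            raise KeyError(f"no reaction {rid!r} in model {self.id!r}") from None

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Check every structural invariant; raise listing all violations."""
        errs: list[str] = []
        met_ids = self.metabolite_ids
        seen = set()
        for mid in met_ids:
            if mid in seen:
                errs.append(f"duplicate metabolite id {mid!r}")
            seen.add(mid)
        rxn_ids = self.reaction_ids
        seen = set()
        for rid in rxn_ids:
            if rid in seen:
                errs.append(f"duplicate reaction id {rid!r}")
            seen.add(rid)
        met_set = set(met_ids)
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                errs.append(
                    f"reaction {r.id!r}: lower_bound {r.lower_bound} > "
                    f"upper_bound {r.upper_bound}"
                )
            if not r.stoichiometry and not r.exchange:
                errs.append(f"reaction {r.id!r}: empty stoichiometry")
            for mid in r.stoichiometry:
                if mid not in met_set:
                    errs.append(
                        f"reaction {r.id!r}: unknown metabolite {mid!r}"
                    )
        if self.objective not in set(rxn_ids):
            errs.append(f"objective reaction {self.objective!r} not in model")
        rxn_set = set(rxn_ids)
        for fr in self.flux_ratios:
            for rid in (fr.numerator, fr.denominator):
                if rid not in rxn_set:
                    errs.append(f"flux ratio references unknown reaction {rid!r}")
        if errs:
            raise ModelValidationError(errs)

    # -- numerics --------------------------------------------------------
    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S matrix, metabolites x reactions.

        Exchange reactions contribute their (one-sided) stoichiometry like
        any other; boundary metabolites simply do not appear.
        """
        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for mid, coeff in r.stoichiometry.items():
                S[met_index[mid], j] = coeff
        return S

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "metabolites": [
                {"id": m.id, "name": m.name, "compartment": m.compartment}
                for m in self.metabolites
            ],
            "reactions": [
                {
                    "id": r.id,
                    "name": r.name,
                    "stoichiometry": dict(r.stoichiometry),
                    "lower_bound": r.lower_bound,
                    "upper_bound": r.upper_bound,
                    "pathway": r.pathway,
                    "compartment": r.compartment,
                    "genes": list(r.genes),
                    "exchange": r.exchange,
                }
                for r in self.reactions
            ],
            "objective": self.objective,
            "flux_ratios": [
                {
                    "numerator": fr.numerator,
                    "denominator": fr.denominator,
                    "ratio": fr.ratio,
                }
                for fr in self.flux_ratios
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n"
        )

    @classmethod
    def from_dict(cls, d: dict) -> "StoichiometricModel":
        return cls(
            id=d.get("id", "model"),
            metabolites=[
                Metabolite(
                    id=m["id"],
                    name=m.get("name", ""),
                    compartment=m.get("compartment", "c"),
                )
                for m in d["metabolites"]
            ],
            reactions=[
                Reaction(
                    id=r["id"],
                    name=r.get("name", ""),
                    stoichiometry={
                        k: float(v) for k, v in r["stoichiometry"].items()
                    },
                    lower_bound=float(r.get("lower_bound", 0.0)),
                    upper_bound=float(r.get("upper_bound", 1000.0)),
                    pathway=r.get("pathway", ""),
                    compartment=r.get("compartment", ""),
                    genes=list(r.get("genes", [])),
                    exchange=bool(r.get("exchange", False)),
                )
                for r in d["reactions"]
            ],
            objective=d["objective"],
            flux_ratios=[
                FluxRatioConstraint(
                    numerator=fr["numerator"],
                    denominator=fr["denominator"],
                    ratio=float(fr["ratio"]),
                )
                for fr in d.get("flux_ratios", [])
            ],
        )


def load_model(path: str | Path) -> StoichiometricModel:
    """Load a model from JSON (``.json``) or SBML (anything else)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        return StoichiometricModel.from_dict(json.loads(path.read_text()))
    return load_sbml(path)


def load_sbml(path: str | Path) -> StoichiometricModel:
    """Import an SBML Level-3 core model (FBC bounds and objective).

    Gene associations are flattened to the set of referenced gene
    products (any-gene-suffices semantics).  Requires python-libsbml.
    """
    try:
        import libsbml
    except ImportError as exc:  # pragma: no cover
        raise ImportError("SBML import requires python-libsbml") from exc

    doc = libsbml.readSBMLFromString(Path(path).read_text())
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ModelValidationError(
            [doc.getError(i).getMessage()
             for i in range(doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR))]
        )
    sb = doc.getModel()
    fbc = sb.getPlugin("fbc")

    params = {
        sb.getParameter(i).getId(): sb.getParameter(i).getValue()
        for i in range(sb.getNumParameters())
    }
    mets = [
        Metabolite(
            id=sb.getSpecies(i).getId(),
            name=sb.getSpecies(i).getName() or "",
            compartment=sb.getSpecies(i).getCompartment() or "c",
        )
        for i in range(sb.getNumSpecies())
        if not sb.getSpecies(i).getBoundaryCondition()
    ]
    met_set = {m.id for m in mets}

    def _genes(rx) -> list[str]:
        plug = rx.getPlugin("fbc")
        if plug is None or plug.getGeneProductAssociation() is None:
            return []
        out: list[str] = []

        def walk(node):
            if node is None:
                return
            if hasattr(node, "getGeneProduct") and node.isGeneProductRef():
                gp = fbc.getGeneProduct(node.getGeneProduct())
                out.append(gp.getLabel() or gp.getId())
                return
            for i in range(node.getNumAssociations()):
                walk(node.getAssociation(i))

        walk(plug.getGeneProductAssociation().getAssociation())
        return sorted(set(out))

    rxns = []
    for i in range(sb.getNumReactions()):
        rx = sb.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            if sr.getSpecies() in met_set:
                stoich[sr.getSpecies()] = (
                    stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
                )
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            if sr.getSpecies() in met_set:
                stoich[sr.getSpecies()] = (
                    stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
                )
        plug = rx.getPlugin("fbc")
        lb = params.get(plug.getLowerFluxBound(), -1000.0) if plug else -1000.0
        ub = params.get(plug.getUpperFluxBound(), 1000.0) if plug else 1000.0
        rxns.append(
            Reaction(
                id=rx.getId(),
                name=rx.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                genes=_genes(rx),
                exchange=not stoich or all(
                    s == 0 for s in stoich.values()
                ) or rx.getId().lower().startswith(("ex_", "r_ex_")),
            )
        )

    objective = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        if obj.getNumFluxObjectives() > 0:
            objective = obj.getFluxObjective(0).getReaction()
    if objective is None:
        raise ModelValidationError(["SBML model has no FBC objective"])

    return StoichiometricModel(
        id=sb.getId() or "sbml_model",
        metabolites=mets,
        reactions=rxns,
        objective=objective,
    )
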