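"""Flux-change values, ±1 congruence scoring, and map export.

The flux-change value of a reaction summarizes its FVA interval shift
between the two accessions: the mean of the changes of the absolute
lower and upper bounds,

    fcv = ((|vmin_A| - |vmin_B|) + (|vmax_A| - |vmax_B|)) / 2 ,

positive when net flux is higher in the high-lipid accession A.  A
reaction is flux-responsive when |fcv| >= epsilon (default 1e-7
μmol/h).  For each (significant transcript, responsive reaction) pair
the congruence is +1 when the transcript log2 fold change and the
flux-change value share a sign, -1 otherwise.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from fluxcord.fva import EPSILON, FluxBoundsSet, ResponsivenessCall
from fluxcord.model import StoichiometricModel


def flux_change_value(
    bounds_a: FluxBoundsSet,
    bounds_b: FluxBoundsSet,
    eps: float = EPSILON,
) -> pd.DataFrame:
    """Per-reaction flux-change values and responsiveness flags.

    Returns a frame indexed by reaction_id with slope_min, slope_max,
    flux_change_value and responsive.  Antisymmetric: swapping the
    accessions negates every value.
    """
    ra, rb = set(bounds_a.bounds.index), set(bounds_b.bounds.index)
    if ra != rb:
        raise ValueError("mismatched reaction sets between accessions")
    a = bounds_a.bounds
    b = bounds_b.bounds.reindex(a.index)
    slope_min = a["vmin"].abs() - b["vmin"].abs()
    slope_max = a["vmax"].abs() - b["vmax"].abs()
    fcv = (slope_min + slope_max) / 2.0
    return pd.DataFrame(
        {
            "slope_min": slope_min,
            "slope_max": slope_max,
            "flux_change_value": fcv,
            "responsive": fcv.abs() >= eps,
        },
        index=a.index,
    )


def congruence_score(
    de: pd.DataFrame,
    transcript_to_gene: pd.Series,
    gene_to_reactions: pd.DataFrame,
    fcv: pd.DataFrame,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """±1 congruence for significant-transcript / responsive-reaction pairs.

    ``de`` is a differential-expression frame (index transcript_id,
    columns log2fc and pvalue); transcripts reach reactions through the
    GPR tables.  Only pairs where the transcript p-value is below
    ``p_threshold`` and the reaction is flux-responsive are emitted.
    A transcript with log2fc exactly 0 scores -1 (no co-signed change).
    """
    sig = de[de["pvalue"] < p_threshold]
    responsive = fcv[fcv["responsive"]]
    gene_rxns = gene_to_reactions[
        gene_to_reactions["reaction_id"].isin(responsive.index)
    ]
    rows = []
    genes = transcript_to_gene.reindex(sig.index)
    for tid, gene in genes.dropna().items():
        for rxn in gene_rxns.loc[gene_rxns["gene_id"] == gene, "reaction_id"]:
            lfc = float(sig.loc[tid, "log2fc"])
            value = float(responsive.loc[rxn, "flux_change_value"])
            congr = 1 if (lfc > 0) == (value > 0) and lfc != 0 else -1
            rows.append(
                {
                    "reaction_id": rxn,
                    "transcript_id": tid,
                    "log2fc": lfc,
                    "flux_change_value": value,
                    "congruence": congr,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "reaction_id",
            "transcript_id",
            "log2fc",
            "flux_change_value",
            "congruence",
        ],
    )


def _flux_direction(call: ResponsivenessCall) -> str:
    """Combined flux direction with N bounds ignored (T/S/N/X)."""
    return call.combined


def summarize_concordance(
    reaction_calls: pd.DataFrame,
    flux_calls: list[ResponsivenessCall],
) -> dict:
    """Cross-tabulate reaction-level expression calls with flux direction.

    ``reaction_calls`` is indexed by reaction_id with a "call" column
    (T/S/N/X from aggregation).  A reaction is direction-matched when
    its expression call equals the combined flux responsiveness (mixed
    T/S flux bounds = X never match).  Returns counts and the matched
    reaction list.
    """
    flux_by_rxn = {c.reaction_id: _flux_direction(c) for c in flux_calls}
    expr = reaction_calls["call"]
    n_t = int((expr == "T").sum())
    n_s = int((expr == "S").sum())
    matched_t: list[str] = []
    matched_s: list[str] = []
    for rxn, call in expr.items():
        fdir = flux_by_rxn.get(rxn)
        if call == "T" and fdir == "T":
            matched_t.append(str(rxn))
        elif call == "S" and fdir == "S":
            matched_s.append(str(rxn))
    return {
        "n_expression_T": n_t,
        "n_expression_S": n_s,
        "n_matched_T": len(matched_t),
        "n_matched_S": len(matched_s),
        "n_matched": len(matched_t) + len(matched_s),
        "matched_T": matched_t,
        "matched_S": matched_s,
    }


def export_map(
    model: StoichiometricModel,
    congruence: pd.DataFrame,
    fcv: pd.DataFrame,
    path: str | Path,
) -> nx.Graph:
    """Write the pathway/compartment-grouped reaction map as GML.

    One node per model reaction, keyed by reaction id, with pathway and
    compartment grouping attributes, the per-transcript congruence
    values (comma-joined, GML has no list type), and a flux_direction
    frame attribute ("increase"/"decrease"/"none" in accession A).
    Returns the graph; edges connect reactions sharing a metabolite so
    the map is a connected network rather than bare nodes.
    """
    g = nx.Graph()
    by_rxn = (
        congruence.groupby("reaction_id")["congruence"].apply(list).to_dict()
        if len(congruence)
        else {}
    )
    for r in model.reactions:
        value = (
            float(fcv.loc[r.id, "flux_change_value"]) if r.id in fcv.index else 0.0
        )
        responsive = bool(fcv.loc[r.id, "responsive"]) if r.id in fcv.index else False
        direction = (
            "increase" if responsive and value > 0
            else "decrease" if responsive and value < 0
            else "none"
        )
        scores = by_rxn.get(r.id, [])
        g.add_node(
            r.id,
            pathway=r.pathway or "unassigned",
            compartment=r.compartment or "unassigned",
            flux_change_value=value,
            flux_direction=direction,
            congruence=",".join(f"{s:+d}" for s in scores),
            n_transcripts=len(scores),
        )
    met_rxns: dict[str, list[str]] = {}
    for r in model.reactions:
        for mid in r.stoichiometry:
            met_rxns.setdefault(mid, []).append(r.id)
    for rxns in met_rxns.values():
        for a, b in zip(rxns, rxns[1:]):
            g.add_edge(a, b)
    nx.write_gml(g, str(path))
    return g
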