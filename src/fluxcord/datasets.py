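"""Shipped worked-example fixtures.

Small machine-readable tables from the published two-accession oilseed
embryo study that the pipeline's aggregation and concordance stages can
be exercised against without any external data: the 27
expression/flux direction-matched reactions with their per-gene call
strings and flux-bound responsiveness labels, the per-functional-
category gene-call counts, and the dataset-level bookkeeping counts.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from fluxcord.aggregate import combine_calls, parse_call_string
from fluxcord.fva import ResponsivenessCall, combine_bound_calls


def _read(name: str) -> pd.DataFrame:
    with resources.files("fluxcord.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_matched_reactions() -> pd.DataFrame:
    """The 27 direction-matched reactions (call strings + flux labels)."""
    return _read("matched_reactions.tsv")


def load_category_counts() -> pd.DataFrame:
    """Per-functional-category published counts of gene-level S/T calls."""
    return _read("functional_categories.tsv")


def load_transcriptome_summary() -> pd.Series:
    """Dataset-level bookkeeping counts, keyed by statistic name."""
    df = _read("transcriptome_summary.tsv")
    return df.set_index("statistic")["value"]


def matched_reaction_calls(
    table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[ResponsivenessCall]]:
    """Run the call-string fixture through the aggregation machinery.

    Parses each reaction's per-gene call string, combines transcript
    calls per gene and gene calls per reaction with the stringent rule,
    and builds flux responsiveness calls from the lower;upper bound
    labels.  Returns (reaction expression calls indexed by the fixture
    abbreviation, flux calls).
    """
    if table is None:
        table = load_matched_reactions()
    expr_rows = []
    flux_calls = []
    for _, row in table.iterrows():
        groups = parse_call_string(row["call_string"])
        gene_calls = []
        for g in groups:
            if g == ["X"]:
                gene_calls.append("X")
            elif not g:
                gene_calls.append("N")
            else:
                gene_calls.append(combine_calls(g))
        expr_rows.append(
            {"reaction_id": row["abbreviation"],
             "call": combine_calls(gene_calls)}
        )
        lo, hi = str(row["responsiveness"]).split(";")
        flux_calls.append(
            ResponsivenessCall(
                reaction_id=str(row["abbreviation"]),
                lower_call=lo,
                upper_call=hi,
                combined=combine_bound_calls(lo, hi),
            )
        )
    expr = pd.DataFrame(expr_rows).set_index("reaction_id")
    return expr, flux_calls
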