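"""Transcript -> gene -> reaction call aggregation and tabulation.

Significance calls are combined with maximum stringency: conflicting
calls at one level (both T and S present) render the next level
non-significant (N).  "X" marks genes for which no transcripts were
found; X and N are neutral at every level.

The compact call-string dialect used for worked examples writes one
parenthesis group per gene, each group listing the per-transcript
significant calls, e.g. ``"()()(S)(SSS)(SS)()()()()"``; ``"(X)"`` is a
gene with no transcripts found.
"""

from __future__ import annotations

import re
from collections.abc import Iterable

import numpy as np
import pandas as pd

VALID_CALLS = frozenset("TSNX")


def combine_calls(calls: Iterable[str]) -> str:
    """Stringent combination of T/S/N/X calls one level up.

    N and X are ignored; all-T -> T, all-S -> S, mixed T/S -> N,
    nothing left -> N.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("empty call list")
    bad = set(calls) - VALID_CALLS
    if bad:
        raise ValueError(f"unknown call symbols: {sorted(bad)}")
    kept = {c for c in calls if c in ("T", "S")}
    if kept == {"T"}:
        return "T"
    if kept == {"S"}:
        return "S"
    return "N"


_GROUP_RE = re.compile(r"\(([^()]*)\)")


def parse_call_string(text: str) -> list[list[str]]:
    """Parse a per-gene call string into per-gene transcript-call lists.

    ``"(SSS)"`` -> ``[["S","S","S"]]``; ``"()"`` -> ``[[]]``;
    ``"(X)"`` -> ``[["X"]]`` (gene with no transcripts found).
    """
    pos = 0
    groups: list[list[str]] = []
    for m in _GROUP_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(
                f"invalid call string at position {pos}: {text[pos:m.start()]!r}"
            )
        inner = m.group(1)
        if inner == "X":
            groups.append(["X"])
        elif all(c in "TS" for c in inner):
            groups.append(list(inner))
        else:
            raise ValueError(
                f"invalid characters {inner!r} at position {m.start()}"
            )
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"invalid call string at position {pos}: {text[pos:]!r}")
    return groups


def aggregate_to_genes(
    transcript_calls: pd.DataFrame,
    transcript_to_gene: pd.Series,
    normalized_sums: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Combine transcript calls per gene; attach summed-count agreement.

    Parameters
    ----------
    transcript_calls : frame indexed by transcript_id with a "call"
        column (T/S/N).
    transcript_to_gene : Series transcript_id -> gene_id.
    normalized_sums : optional frame indexed by transcript_id with
        columns sum_A / sum_B of normalized counts; when given, per-gene
        sums and the agreement flag (call direction matches the larger
        sum, strict inequality; ties disagree) are added.

    Transcripts missing from the map are excluded (warning via the
    returned attrs["unmapped"]).
    """
    mapped = transcript_calls.index.isin(transcript_to_gene.index)
    unmapped = list(transcript_calls.index[~mapped])
    tc = transcript_calls.loc[mapped].copy()
    tc["gene_id"] = transcript_to_gene.reindex(tc.index).values

    rows = []
    for gene, grp in tc.groupby("gene_id", sort=True):
        call = combine_calls(grp["call"].tolist())
        row = {"gene_id": gene, "call": call}
        if normalized_sums is not None:
            sums = normalized_sums.reindex(grp.index).fillna(0.0)
            sa, sb = float(sums["sum_A"].sum()), float(sums["sum_B"].sum())
            row["sum_A"] = sa
            row["sum_B"] = sb
            row["agreement"] = (
                (call == "T" and sa > sb) or (call == "S" and sb > sa)
            )
        rows.append(row)
    out = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["call"], index=pd.Index([], name="gene_id")
    )
    out.attrs["unmapped"] = unmapped
    return out


def aggregate_to_reactions(
    gene_calls: pd.DataFrame,
    gene_to_reactions: pd.DataFrame,
) -> pd.DataFrame:
    """Combine gene calls per reaction with the same stringent rule.

    ``gene_to_reactions`` has columns gene_id, reaction_id.  Genes
    absent from ``gene_calls`` count as X (no transcripts found);
    reactions whose genes are all absent — or that have no genes — get
    call "X".
    """
    rows = []
    for rxn, grp in gene_to_reactions.groupby("reaction_id", sort=True):
        genes = grp["gene_id"].tolist()
        calls = [
            str(gene_calls.loc[g, "call"]) if g in gene_calls.index else "X"
            for g in genes
        ]
        if not calls or set(calls) == {"X"}:
            rows.append({"reaction_id": rxn, "call": "X"})
        else:
            rows.append({"reaction_id": rxn, "call": combine_calls(calls)})
    if not rows:
        return pd.DataFrame(columns=["call"], index=pd.Index([], name="reaction_id"))
    return pd.DataFrame(rows).set_index("reaction_id")


def tabulate_categories(
    gene_calls: pd.DataFrame,
    categories: pd.Series,
    not_assigned: str = "not assigned",
) -> pd.DataFrame:
    """Per-category counts of S and T gene calls and the T/S ratio.

    ``categories`` maps gene_id -> functional category (e.g. a MapMan
    BIN code); uncategorized called genes fall into ``not_assigned``.
    Categories with neither S nor T calls are omitted.  The ratio is
    n_T / n_S, reported as inf when n_S is 0 and rounded to 2 decimals.
    """
    called = gene_calls[gene_calls["call"].isin(["T", "S"])]
    cats = categories.reindex(called.index).fillna(not_assigned)
    rows = []
    for cat, grp in called.groupby(cats.values):
        n_s = int((grp["call"] == "S").sum())
        n_t = int((grp["call"] == "T").sum())
        ratio = np.inf if n_s == 0 else round(n_t / n_s, 2)
        rows.append({"category": cat, "n_S": n_s, "n_T": n_t, "ratio_T_S": ratio})
    if not rows:
        return pd.DataFrame(
            columns=["n_S", "n_T", "ratio_T_S"],
            index=pd.Index([], name="category"),
        )
    return pd.DataFrame(rows).set_index("category")
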