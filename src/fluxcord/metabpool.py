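"""Metabolite pooling and flux/metabolite cross-tabulation.

Metabolite measurements come as biological x technical replicates per
accession.  Where the flux analysis lumps several reactions into one
flux value, the corresponding compounds are pooled (e.g. the hexose
phosphates as one aggregate); technical replicates are averaged first,
then member means are summed per biological replicate, and accessions
are compared with a Welch two-sided t-test at p < 0.05 per pool (no
multiplicity correction — shifts are flagged compound-wise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from fluxcord.fva import ResponsivenessCall

#: expected columns of a metabolite measurement table
METABOLITE_COLUMNS = ["compound", "accession", "bio_rep", "tech_rep", "value"]


@dataclass
class PoolDefinition:
    pool_id: str
    members: list[str]
    reaction_id: str = ""  # linked flux group

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"pool {self.pool_id!r} has no members")


def pool_levels(
    measurements: pd.DataFrame,
    pools: list[PoolDefinition],
) -> pd.DataFrame:
    """Per-pool, per-biological-replicate pooled values.

    Technical replicates are averaged within each (compound, accession,
    bio_rep) cell; the pool value is the sum of member means.  Pools
    with a member missing in either accession are flagged incomplete
    and carry NaN values.

    Returns a long frame: pool_id, accession, bio_rep, value, complete.
    """
    missing_cols = set(METABOLITE_COLUMNS) - set(measurements.columns)
    if missing_cols:
        raise ValueError(f"measurement table lacks columns {sorted(missing_cols)}")
    measurements = measurements.assign(
        accession=measurements["accession"].astype(str)
    )
    bio_means = (
        measurements.groupby(["compound", "accession", "bio_rep"])["value"]
        .mean()
        .rename("value")
    )
    accessions = sorted(measurements["accession"].unique())
    rows = []
    for pool in pools:
        present = {
            acc: set(
                measurements.loc[
                    measurements["accession"] == acc, "compound"
                ].unique()
            )
            for acc in accessions
        }
        complete = all(
            m in present[acc] for m in pool.members for acc in accessions
        )
        for acc in accessions:
            reps = sorted(
                measurements.loc[
                    measurements["accession"] == acc, "bio_rep"
                ].unique()
            )
            for rep in reps:
                if complete:
                    value = sum(
                        float(bio_means.loc[(m, acc, rep)])
                        for m in pool.members
                    )
                else:
                    value = np.nan
                rows.append(
                    {
                        "pool_id": pool.pool_id,
                        "accession": acc,
                        "bio_rep": rep,
                        "value": value,
                        "complete": complete,
                    }
                )
    return pd.DataFrame(rows)


def compare_pools(
    pooled: pd.DataFrame,
    accession_a: str,
    accession_b: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t-test per pool between accessions on biological replicates.

    Returns a frame indexed by pool_id with mean_A, mean_B, pvalue,
    significant, direction ("A"/"B"/"none").  Incomplete pools are
    excluded.  Fewer than 2 replicates on either side is an error.
    """
    out = []
    for pool_id, grp in pooled[pooled["complete"]].groupby("pool_id"):
        xa = grp.loc[grp["accession"] == accession_a, "value"].values
        xb = grp.loc[grp["accession"] == accession_b, "value"].values
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(
                f"pool {pool_id!r}: need >=2 biological replicates per "
                f"accession (got {len(xa)} vs {len(xb)})"
            )
        if np.var(xa) == 0 and np.var(xb) == 0:
            p = 1.0 if xa.mean() == xb.mean() else 0.0
        else:
            p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
        sig = p < alpha
        out.append(
            {
                "pool_id": pool_id,
                "mean_A": float(xa.mean()),
                "mean_B": float(xb.mean()),
                "pvalue": p,
                "significant": sig,
                "direction": (
                    "A" if sig and xa.mean() > xb.mean()
                    else "B" if sig else "none"
                ),
            }
        )
    return pd.DataFrame(
        out,
        columns=["pool_id", "mean_A", "mean_B", "pvalue", "significant", "direction"],
    ).set_index("pool_id")


def crosstab_flux_metabolite(
    pool_tests: pd.DataFrame,
    flux_calls: list[ResponsivenessCall],
    pool_links: dict[str, str],
) -> tuple[pd.DataFrame, float]:
    """Cross-tabulate metabolite shifts against flux responsiveness.

    ``pool_links`` maps pool_id -> reaction_id.  Returns the per-pair
    table (flux_changed, flux_direction, metabolite_shifted,
    metabolite_direction, concordant) and the summary fraction of
    flux-changed reactions whose linked pool shifted significantly
    (NaN when no linked reaction changed flux).
    """
    flux_by_rxn = {c.reaction_id: c.combined for c in flux_calls}
    rows = []
    for pool_id, rxn in pool_links.items():
        if pool_id not in pool_tests.index or rxn not in flux_by_rxn:
            continue
        fdir = flux_by_rxn[rxn]
        flux_changed = fdir in ("T", "S")
        test = pool_tests.loc[pool_id]
        shifted = bool(test["significant"])
        # metabolite direction A/B vs flux direction T (A) / S (B)
        concordant = shifted and flux_changed and (
            (fdir == "T" and test["direction"] == "A")
            or (fdir == "S" and test["direction"] == "B")
        )
        rows.append(
            {
                "pool_id": pool_id,
                "reaction_id": rxn,
                "flux_changed": flux_changed,
                "flux_direction": fdir,
                "metabolite_shifted": shifted,
                "metabolite_direction": test["direction"],
                "concordant": concordant,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "pool_id",
            "reaction_id",
            "flux_changed",
            "flux_direction",
            "metabolite_shifted",
            "metabolite_direction",
            "concordant",
        ],
    )
    changed = table[table["flux_changed"]]
    fraction = (
        float(changed["metabolite_shifted"].mean()) if len(changed) else float("nan")
    )
    return table, fraction
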