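"""End-to-end orchestration: FVA -> DE -> aggregation -> concordance -> pools.

A :class:`PipelineConfig` names the inputs (two model
parameterizations, a count matrix, GPR tables, optional categories and
metabolite measurements), the accession labels with the high-lipid
anchor, and the thresholds.  :func:`run_pipeline` executes the stages
in order, writing every artifact into the output directory; identical
config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import fluxcord
from fluxcord import aggregate as agg
from fluxcord import concord, diffexpr, metabpool
from fluxcord.fva import classify_responsiveness, fva, responsiveness_frame
from fluxcord.model import load_model
from fluxcord.synthdata import GPRTables, PoolDefinition

log = logging.getLogger("fluxcord")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class PipelineConfig:
    model_a: str = ""
    model_b: str = ""
    counts: str = ""
    transcript_gene_map: str = ""
    gene_reaction_map: str = ""
    categories: str = ""  # optional TSV: gene_id, category
    metabolites: str = ""  # optional TSV: compound, accession, bio_rep, tech_rep, value
    pools: str = ""  # optional TSV: pool_id, compound, reaction_id
    accessions: list[str] = field(default_factory=lambda: ["3170", "3231"])
    high_lipid: str = "3170"
    padj_threshold: float = 0.01
    fold_threshold: float = 2.0
    flux_epsilon: float = 1e-7
    metabolite_alpha: float = 0.05
    optimality_fraction: float = 1.0
    seed: int = 0
    outdir: str = "fluxcord_out"

    def validate(self) -> None:
        if len(self.accessions) != 2:
            raise ValueError(
                f"exactly two accessions required, got {self.accessions}"
            )
        if self.high_lipid not in self.accessions:
            raise ValueError(
                f"high_lipid {self.high_lipid!r} is not one of {self.accessions}"
            )
        for name in ("padj_threshold", "fold_threshold", "flux_epsilon",
                     "metabolite_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def read_pools(path: str | Path) -> list[PoolDefinition]:
    df = pd.read_csv(path, sep="\t", comment="#")
    pools = []
    for pid, grp in df.groupby("pool_id", sort=True):
        rxn = str(grp["reaction_id"].iloc[0]) if "reaction_id" in grp else ""
        pools.append(
            PoolDefinition(str(pid), grp["compound"].tolist(), rxn)
        )
    return pools


def _table1_stats(
    de: pd.DataFrame,
    gene_calls: pd.DataFrame,
    reaction_calls: pd.DataFrame,
    flux_calls,
    t2g: pd.Series,
) -> pd.DataFrame:
    """Summary statistics in the layout of the headline bookkeeping table."""
    flux_by_rxn = {c.reaction_id: c.combined for c in flux_calls}
    n_transcripts = len(de)
    n_genes = t2g.nunique()
    rows = [
        ("transcripts", "annotated transcripts", n_transcripts),
        ("transcripts", "associated gene identifiers", n_genes),
        ("transcripts", "average transcripts per gene",
         round(n_transcripts / n_genes, 1) if n_genes else 0.0),
        ("transcripts", "T calls (higher in high-lipid accession)",
         int((de["call"] == "T").sum())),
        ("transcripts", "S calls (higher in high-starch accession)",
         int((de["call"] == "S").sum())),
    ]
    for call in ("T", "S"):
        sub = gene_calls[gene_calls["call"] == call]
        rows.append(("genes", f"calls unambiguously combine to {call}", len(sub)))
        if "agreement" in gene_calls.columns:
            rows.append(
                ("genes", f"+ summed expression agrees ({call})",
                 int(sub["agreement"].sum()))
            )
    for call in ("T", "S"):
        sub = reaction_calls[reaction_calls["call"] == call]
        rows.append(
            ("reactions", f"calls unambiguously combine to {call}", len(sub))
        )
        matched = sum(
            1 for rxn in sub.index if flux_by_rxn.get(str(rxn)) == call
        )
        rows.append(("reactions", f"+ flux direction matches ({call})", matched))
    return pd.DataFrame(rows, columns=["level", "statistic", "value"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; write artifacts into ``config.outdir``.

    Returns a dict of the key in-memory results (responsiveness frame,
    DE table, gene/reaction calls, concordance summary, stats table).
    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    acc_a = config.high_lipid
    acc_b = next(a for a in config.accessions if a != acc_a)
    results: dict = {}

    def stage(name):
        log.info("stage %s", name)
        return name

    # -- flux variability ------------------------------------------------
    name = stage("fva")
    try:
        model_a = load_model(config.model_a)
        model_b = load_model(config.model_b)
        bounds_a = fva(model_a, optimality_fraction=config.optimality_fraction,
                       accession=acc_a)
        bounds_b = fva(model_b, optimality_fraction=config.optimality_fraction,
                       accession=acc_b)
        bounds_a.to_tsv(out / "flux_bounds_A.tsv")
        bounds_b.to_tsv(out / "flux_bounds_B.tsv")
        flux_calls = classify_responsiveness(bounds_a, bounds_b,
                                             eps=config.flux_epsilon)
        resp = responsiveness_frame(flux_calls)
        resp.to_csv(out / "flux_responsiveness.tsv", sep="\t")
        results["responsiveness"] = resp
        results["flux_calls"] = flux_calls
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc

    # -- differential expression ----------------------------------------
    name = stage("de")
    try:
        cm = diffexpr.CountMatrix.from_tsv(config.counts)
        if sorted(set(cm.accessions.values())) != sorted(config.accessions):
            raise ValueError(
                f"count matrix accessions {sorted(set(cm.accessions.values()))} "
                f"differ from config {sorted(config.accessions)}"
            )
        de = diffexpr.run_de(cm, accession_a=acc_a,
                             padj_threshold=config.padj_threshold,
                             fold_threshold=config.fold_threshold)
        de.to_csv(out / "differential_expression.tsv", sep="\t")
        results["de"] = de
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc

    # -- aggregation -----------------------------------------------------
    name = stage("aggregate")
    try:
        gpr = GPRTables.read(config.transcript_gene_map, config.gene_reaction_map)
        t2g = gpr.transcript_gene_series
        sf = diffexpr.size_factors(cm.counts)
        z = diffexpr.normalized_counts(cm.counts, sf)
        sums = pd.DataFrame(
            {
                "sum_A": z[cm.samples_of(acc_a)].sum(axis=1),
                "sum_B": z[cm.samples_of(acc_b)].sum(axis=1),
            }
        )
        gene_calls = agg.aggregate_to_genes(de, t2g, sums)
        gene_calls.to_csv(out / "gene_calls.tsv", sep="\t")
        reaction_calls = agg.aggregate_to_reactions(
            gene_calls, gpr.gene_to_reaction
        )
        reaction_calls.to_csv(out / "reaction_calls.tsv", sep="\t")
        results["gene_calls"] = gene_calls
        results["reaction_calls"] = reaction_calls
        if config.categories:
            cats = pd.read_csv(config.categories, sep="\t", comment="#")
            cat_map = cats.set_index("gene_id")["category"]
            tab = agg.tabulate_categories(gene_calls, cat_map)
            tab.to_csv(out / "category_summary.tsv", sep="\t")
            results["categories"] = tab
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc

    # -- concordance -----------------------------------------------------
    name = stage("concord")
    try:
        fcv = concord.flux_change_value(bounds_a, bounds_b,
                                        eps=config.flux_epsilon)
        fcv.to_csv(out / "flux_change_values.tsv", sep="\t")
        records = concord.congruence_score(
            de, t2g, gpr.gene_to_reaction, fcv,
            p_threshold=config.padj_threshold,
        )
        records.to_csv(out / "congruence.tsv", sep="\t", index=False)
        summary = concord.summarize_concordance(reaction_calls, flux_calls)
        (out / "concordance_summary.json").write_text(
            json.dumps(summary, indent=1) + "\n"
        )
        concord.export_map(model_a, records, fcv, out / "reaction_map.gml")
        results["congruence"] = records
        results["concordance"] = summary
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc

    # -- metabolite pools -------------------------------------------------
    if config.metabolites and config.pools:
        name = stage("metab")
        try:
            meas = pd.read_csv(config.metabolites, sep="\t", comment="#")
            pools = read_pools(config.pools)
            pooled = metabpool.pool_levels(meas, pools)
            pooled.to_csv(out / "pooled_metabolites.tsv", sep="\t", index=False)
            tests = metabpool.compare_pools(pooled, acc_a, acc_b,
                                            alpha=config.metabolite_alpha)
            tests.to_csv(out / "pool_tests.tsv", sep="\t")
            links = {p.pool_id: p.reaction_id for p in pools if p.reaction_id}
            crosstab, fraction = metabpool.crosstab_flux_metabolite(
                tests, flux_calls, links
            )
            crosstab.to_csv(out / "flux_metabolite_crosstab.tsv", sep="\t",
                            index=False)
            results["pool_tests"] = tests
            results["crosstab"] = crosstab
            results["shift_fraction"] = fraction
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

    # -- report ------------------------------------------------------------
    name = stage("report")
    try:
        stats = _table1_stats(de, gene_calls, reaction_calls, flux_calls, t2g)
        stats.to_csv(out / "summary_statistics.tsv", sep="\t", index=False)
        results["stats"] = stats
        run_log = {
            "fluxcord_version": fluxcord.__version__,
            "seed": config.seed,
            "thresholds": {
                "padj": config.padj_threshold,
                "fold": config.fold_threshold,
                "flux_epsilon": config.flux_epsilon,
                "metabolite_alpha": config.metabolite_alpha,
            },
            "accessions": {"high_lipid": acc_a, "high_starch": acc_b},
            "config": asdict(config),
        }
        (out / "run_log.json").write_text(json.dumps(run_log, indent=1) + "\n")
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc
    return results


def write_scenario(scenario, outdir: str | Path) -> PipelineConfig:
    """Generate all synthetic inputs for a scenario and return a config.

    Runs the generators (model pair, FVA-based responsiveness truth,
    GPR tables, planted counts, metabolite pools) and writes the input
    files a pipeline run consumes.
    """
    from fluxcord.synthdata import (
        default_pools,
        make_gpr,
        make_model_pair,
        plant_concordance,
        simulate_counts,
        simulate_metabolites,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pair = make_model_pair(scenario)
    pair.model_a.to_json(outdir / "model_A.json")
    pair.model_b.to_json(outdir / "model_B.json")

    bounds_a = fva(pair.model_a, accession=scenario.accession_a)
    bounds_b = fva(pair.model_b, accession=scenario.accession_b)
    flux_calls = classify_responsiveness(bounds_a, bounds_b)

    gpr = make_gpr(scenario, pair.model_a)
    gpr.write(outdir / "transcript_gene.tsv", outdir / "gene_reaction.tsv")
    truth = plant_concordance(
        flux_calls, scenario.concordance_fraction, gpr, scenario
    )
    with open(outdir / "gene_truth.tsv", "w") as fh:
        fh.write("# planted gene-level truth\n")
        truth.to_csv(fh, sep="\t", index=False)
    cm, transcript_truth = simulate_counts(gpr, truth, scenario)
    cm.to_tsv(outdir / "counts.tsv")
    with open(outdir / "transcript_truth.tsv", "w") as fh:
        fh.write("# planted transcript-level truth\n")
        transcript_truth.to_csv(fh, sep="\t", index=False)

    pools = default_pools()
    meas, metab_truth = simulate_metabolites(pools, scenario)
    meas.to_csv(outdir / "metabolites.tsv", sep="\t", index=False)
    metab_truth.to_csv(outdir / "metabolite_truth.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"pool_id": p.pool_id, "compound": c, "reaction_id": p.reaction_id}
            for p in pools
            for c in p.members
        ]
    ).to_csv(outdir / "pools.tsv", sep="\t", index=False)

    return PipelineConfig(
        model_a=str(outdir / "model_A.json"),
        model_b=str(outdir / "model_B.json"),
        counts=str(outdir / "counts.tsv"),
        transcript_gene_map=str(outdir / "transcript_gene.tsv"),
        gene_reaction_map=str(outdir / "gene_reaction.tsv"),
        metabolites=str(outdir / "metabolites.tsv"),
        pools=str(outdir / "pools.tsv"),
        accessions=[scenario.accession_a, scenario.accession_b],
        high_lipid=scenario.accession_a,
        seed=scenario.seed,
        outdir=str(outdir / "results"),
    )
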