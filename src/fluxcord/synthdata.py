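"""Synthetic inputs with the statistical structure the pipeline assumes.

Generates everything the analysis consumes so every stage is testable
without the deposited sequencing data: a compartmentalized toy
central-metabolism network whose two biomass parameterizations differ
in lipid vs. starch output (mirroring a high-lipid and a high-starch
accession), gene-protein-reaction tables with multi-transcript genes
(mean ~4.7 transcripts per gene, matching allopolyploid homeolog
redundancy), negative-binomial two-accession count matrices with
quota-planted concordant/discordant differential expression, and
replicate metabolite tables with planted pool shifts.

Every generator is a pure function of the scenario seed: fixed seed,
identical output, byte-identical files.  The toy network topology is a
versioned JSON fixture shipped with the package; generators
re-parameterize its biomass but never regenerate topology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from fluxcord.diffexpr import CountMatrix
from fluxcord.fva import ResponsivenessCall
from fluxcord.metabpool import PoolDefinition
from fluxcord.model import (
    FluxRatioConstraint,
    Metabolite,
    Reaction,
    StoichiometricModel,
)

CORE_MODEL_RESOURCE = "toy_central_metabolism_v1.json"
#: reactions in the core fixture
CORE_N_REACTIONS = 23

# rng stream tags so each generator draws independently of the others
_STREAM_MODEL, _STREAM_GPR, _STREAM_TRUTH, _STREAM_COUNTS, _STREAM_METAB = range(5)


@dataclass
class ScenarioConfig:
    """Study conditions for a synthetic scenario.

    Defaults mirror the two-accession embryo-culture design: three
    biological replicates per accession, on average 4.7 transcripts per
    gene identifier, biomass of the high-lipid variant A at 40% lipid /
    10% starch against 25% / 25% for the high-starch variant B.
    """

    seed: int = 0
    n_reactions: int = CORE_N_REACTIONS
    n_genes_per_reaction: tuple[int, int] = (1, 3)
    transcripts_per_gene_mean: float = 4.7
    n_background_genes: int = 1000
    missing_gene_rate: float = 0.02
    n_replicates: int = 3
    dispersion: float = 0.05
    depth_spread: float = 0.15
    concordance_fraction: float = 0.8
    effect_log2fc: float = 2.0
    background_de_fraction: float = 0.05
    base_mean: float = 200.0
    base_log_sd: float = 1.0
    lipid_fraction_a: float = 0.40
    starch_fraction_a: float = 0.10
    lipid_fraction_b: float = 0.25
    starch_fraction_b: float = 0.25
    accession_a: str = "3170"
    accession_b: str = "3231"
    n_bio_reps: int = 3
    n_tech_reps: int = 5
    bio_cv: float = 0.10
    tech_cv: float = 0.05
    metab_shift_fold: float = 4.0
    metab_shift_fraction: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.concordance_fraction <= 1.0:
            raise ValueError("concordance_fraction must be in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.depth_spread < 0:
            raise ValueError("depth_spread must be >= 0")
        for name in ("n_reactions", "n_background_genes", "n_replicates",
                     "n_bio_reps", "n_tech_reps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.transcripts_per_gene_mean < 1:
            raise ValueError("transcripts_per_gene_mean must be >= 1")
        for tag in ("a", "b"):
            lip = getattr(self, f"lipid_fraction_{tag}")
            sta = getattr(self, f"starch_fraction_{tag}")
            if not (0 <= lip <= 1 and 0 <= sta <= 1 and lip + sta <= 1):
                raise ValueError(
                    f"variant {tag}: fractions must lie in [0,1] with "
                    f"lipid + starch <= 1 (got {lip}, {sta})"
                )

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


# ---------------------------------------------------------------------------
# model pair


def load_core_network() -> StoichiometricModel:
    """The versioned toy central-metabolism fixture (sucrose uptake,
    cytosolic/plastidic glycolysis, pentose-phosphate, TCA, fatty-acid/
    TAG synthesis, starch synthesis, amino-acid/protein synthesis, and
    inter-compartment transporters across cytosol/plastid/mitochondrion).
    """
    text = (
        resources.files("fluxcord.data").joinpath(CORE_MODEL_RESOURCE).read_text()
    )
    return StoichiometricModel.from_dict(json.loads(text))


@dataclass
class ModelPair:
    """One network topology under two biomass parameterizations."""

    model_a: StoichiometricModel
    model_b: StoichiometricModel
    biomass_params: dict[str, dict[str, float]]
    ratio_constraints: list[FluxRatioConstraint]

    def model_for(self, which: str) -> StoichiometricModel:
        return self.model_a if which == "A" else self.model_b


def _with_biomass(
    base: StoichiometricModel,
    lipid: float,
    starch: float,
    extra_demands: dict[str, float],
    variant_id: str,
) -> StoichiometricModel:
    d = base.to_dict()
    d["id"] = f"{base.id}_{variant_id}"
    protein = 1.0 - lipid - starch
    for r in d["reactions"]:
        if r["id"] == "biomass":
            stoich = {"TAG_c": -lipid, "Starch_p": -starch, "Prot_c": -protein}
            stoich = {k: v for k, v in stoich.items() if v != 0.0}
            stoich.update({m: -w for m, w in extra_demands.items()})
            r["stoichiometry"] = stoich
    return StoichiometricModel.from_dict(d)


def make_model_pair(config: ScenarioConfig) -> ModelPair:
    """Build the two-accession model pair, scaled to ~n_reactions.

    Beyond the 22-reaction core, extra nutrient-assimilation modules
    (uptake -> transport -> assimilation, 3 reactions each) are appended
    until ``n_reactions`` is reached; each module feeds the biomass with
    a demand coefficient that differs between the variants, so its whole
    chain is flux-responsive in a seeded direction.  Raises if either
    parameterization is infeasible or has zero growth, naming the
    blocking constraint.
    """
    rng = config.rng(_STREAM_MODEL)
    base = load_core_network()
    n_modules = max(0, -(-(config.n_reactions - CORE_N_REACTIONS) // 3))

    mets = list(base.metabolites)
    rxns = list(base.reactions)
    demands_a: dict[str, float] = {}
    demands_b: dict[str, float] = {}
    for k in range(n_modules):
        xc, xp, xb = f"X{k:03d}_c", f"X{k:03d}_p", f"Xb{k:03d}_p"
        mets += [
            Metabolite(xc, f"nutrient {k} (cytosol)", "c"),
            Metabolite(xp, f"nutrient {k} (plastid)", "p"),
            Metabolite(xb, f"assimilate {k} (plastid)", "p"),
        ]
        rxns += [
            Reaction(
                id=f"Ex_X{k:03d}", stoichiometry={xc: 1.0},
                lower_bound=0.0, upper_bound=1000.0,
                pathway="nutrient_uptake", compartment="c", exchange=True,
            ),
            Reaction(
                id=f"XT{k:03d}_cp", stoichiometry={xc: -1.0, xp: 1.0},
                lower_bound=0.0, upper_bound=1000.0,
                pathway="transport", compartment="cp",
            ),
            Reaction(
                id=f"XS{k:03d}_p", stoichiometry={xp: -1.0, xb: 1.0},
                lower_bound=0.0, upper_bound=1000.0,
                pathway="nutrient_assimilation", compartment="p",
            ),
        ]
        w = 0.05
        # seeded direction: higher demand in A ("T"-ward) or in B
        if rng.random() < 0.5:
            demands_a[xb], demands_b[xb] = w * 1.6, w / 1.6
        else:
            demands_a[xb], demands_b[xb] = w / 1.6, w * 1.6

    topo = StoichiometricModel(
        id=base.id, metabolites=mets, reactions=rxns,
        objective=base.objective, flux_ratios=base.flux_ratios,
    )
    model_a = _with_biomass(
        topo, config.lipid_fraction_a, config.starch_fraction_a, demands_a, "A"
    )
    model_b = _with_biomass(
        topo, config.lipid_fraction_b, config.starch_fraction_b, demands_b, "B"
    )

    from fluxcord.fva import InfeasibleModelError, fba

    for label, m in (("A", model_a), ("B", model_b)):
        try:
            opt = fba(m).objective_value
        except InfeasibleModelError as exc:
            raise InfeasibleModelError(
                f"variant {label} infeasible under biomass parameterization "
                f"{m.reaction('biomass').stoichiometry}: {exc}"
            ) from exc
        if opt <= 0:
            raise InfeasibleModelError(
                f"variant {label}: zero optimum — blocking constraint is the "
                f"substrate uptake bound (Ex_suc <= "
                f"{m.reaction('Ex_suc').upper_bound}) or a zero biomass demand"
            )

    return ModelPair(
        model_a=model_a,
        model_b=model_b,
        biomass_params={
            "A": {"lipid": config.lipid_fraction_a,
                  "starch": config.starch_fraction_a},
            "B": {"lipid": config.lipid_fraction_b,
                  "starch": config.starch_fraction_b},
        },
        ratio_constraints=list(base.flux_ratios),
    )


# ---------------------------------------------------------------------------
# GPR tables


@dataclass
class GPRTables:
    """transcript -> gene and gene -> reaction association tables."""

    transcript_to_gene: pd.DataFrame  # columns: transcript_id, gene_id
    gene_to_reaction: pd.DataFrame  # columns: gene_id, reaction_id
    missing_genes: list[str] = field(default_factory=list)

    @property
    def transcript_gene_series(self) -> pd.Series:
        return self.transcript_to_gene.set_index("transcript_id")["gene_id"]

    def write(self, t2g_path: str | Path, g2r_path: str | Path) -> None:
        with open(t2g_path, "w") as fh:
            fh.write("# transcript -> gene map\n")
            self.transcript_to_gene.to_csv(fh, sep="\t", index=False)
        with open(g2r_path, "w") as fh:
            fh.write("# gene -> reaction map; missing_transcripts flags "
                     "genes with no transcripts found (X)\n")
            g2r = self.gene_to_reaction.copy()
            g2r["missing_transcripts"] = g2r["gene_id"].isin(self.missing_genes)
            g2r.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read(cls, t2g_path: str | Path, g2r_path: str | Path) -> "GPRTables":
        t2g = pd.read_csv(t2g_path, sep="\t", comment="#")
        g2r = pd.read_csv(g2r_path, sep="\t", comment="#")
        missing = (
            g2r.loc[g2r["missing_transcripts"], "gene_id"].tolist()
            if "missing_transcripts" in g2r.columns
            else []
        )
        return cls(
            transcript_to_gene=t2g,
            gene_to_reaction=g2r[["gene_id", "reaction_id"]],
            missing_genes=sorted(set(missing)),
        )


def _gene_id(i: int) -> str:
    return f"AT{1 + i % 5}G{(10 + i) * 10:05d}"


def make_gpr(config: ScenarioConfig, model: StoichiometricModel) -> GPRTables:
    """Generate GPR tables for a model plus unlinked background genes.

    Each enzymatic reaction gets 1..k distinct genes (seeded); each gene
    maps to one reaction.  Every transcript maps to exactly one gene;
    transcripts per gene are 1 + Poisson(mean − 1).  A small seeded
    fraction of reaction genes is emitted with no transcripts at all
    ("missing", the X marker downstream).
    """
    rng = config.rng(_STREAM_GPR)
    lo, hi = config.n_genes_per_reaction
    gene_rows = []
    i = 0
    for r in model.reactions:
        if r.exchange or r.id == model.objective:
            continue
        for _ in range(int(rng.integers(lo, hi + 1))):
            gene_rows.append({"gene_id": _gene_id(i), "reaction_id": r.id})
            i += 1
    background = [_gene_id(i + j) for j in range(config.n_background_genes)]

    g2r = pd.DataFrame(gene_rows, columns=["gene_id", "reaction_id"])
    reaction_genes = g2r["gene_id"].tolist()
    missing = [
        g for g in reaction_genes if rng.random() < config.missing_gene_rate
    ]
    missing_set = set(missing)

    t_rows = []
    for gene in reaction_genes + background:
        if gene in missing_set:
            continue
        n_t = 1 + int(rng.poisson(config.transcripts_per_gene_mean - 1.0))
        for j in range(n_t):
            t_rows.append({"transcript_id": f"{gene}_t{j + 1}", "gene_id": gene})
    return GPRTables(
        transcript_to_gene=pd.DataFrame(t_rows),
        gene_to_reaction=g2r,
        missing_genes=sorted(missing_set),
    )


# ---------------------------------------------------------------------------
# planted truth


def plant_concordance(
    flux_calls: list[ResponsivenessCall],
    beta: float,
    gpr: GPRTables,
    config: ScenarioConfig,
) -> pd.DataFrame:
    """Quota-planted gene-level truth from flux responsiveness calls.

    Exactly ⌊beta·K⌋ of the K flux-responsive reactions (combined call
    T or S) are made congruent — their genes get differential expression
    in the direction of the flux change — and the remainder get the
    opposite direction.  Genes of non-responsive reactions are null (N);
    a seeded fraction of background genes gets DE in a random direction.

    Returns a frame with columns gene_id, call, effect_log2fc,
    reaction_id, congruent.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must be in [0, 1]")
    rng = config.rng(_STREAM_TRUTH)
    responsive = [c for c in flux_calls if c.combined in ("T", "S")]
    order = rng.permutation(len(responsive))
    quota = int(np.floor(beta * len(responsive)))
    congruent_idx = {int(i) for i in order[:quota]}

    flip = {"T": "S", "S": "T"}
    rows = []
    assigned: set[str] = set()
    for i, c in enumerate(responsive):
        congruent = i in congruent_idx
        direction = c.combined if congruent else flip[c.combined]
        for g in gpr.gene_to_reaction.loc[
            gpr.gene_to_reaction["reaction_id"] == c.reaction_id, "gene_id"
        ]:
            if g in assigned:
                continue
            assigned.add(g)
            rows.append(
                {
                    "gene_id": g,
                    "call": direction,
                    "effect_log2fc": config.effect_log2fc,
                    "reaction_id": c.reaction_id,
                    "congruent": congruent,
                }
            )
    null_rxns = {c.reaction_id for c in flux_calls if c.combined not in ("T", "S")}
    for g, rxn in zip(
        gpr.gene_to_reaction["gene_id"], gpr.gene_to_reaction["reaction_id"]
    ):
        if g not in assigned and rxn in null_rxns:
            assigned.add(g)
            rows.append(
                {"gene_id": g, "call": "N", "effect_log2fc": 0.0,
                 "reaction_id": rxn, "congruent": False}
            )
    all_genes = pd.unique(
        pd.concat(
            [gpr.transcript_to_gene["gene_id"], gpr.gene_to_reaction["gene_id"]]
        )
    )
    for g in all_genes:
        if g in assigned:
            continue
        if rng.random() < config.background_de_fraction:
            rows.append(
                {
                    "gene_id": g,
                    "call": "T" if rng.random() < 0.5 else "S",
                    "effect_log2fc": config.effect_log2fc,
                    "reaction_id": "",
                    "congruent": False,
                }
            )
        else:
            rows.append(
                {"gene_id": g, "call": "N", "effect_log2fc": 0.0,
                 "reaction_id": "", "congruent": False}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# counts


def simulate_counts(
    gpr: GPRTables,
    truth: pd.DataFrame,
    config: ScenarioConfig,
) -> tuple[CountMatrix, pd.DataFrame]:
    """NB counts for every transcript under the planted gene truth.

    μ_ij = base_i · depth_j · 2^(±effect/2) with the sign set by the
    gene's planted direction (T: up in accession A), counts drawn
    NB(μ, α) via the gamma-Poisson mixture (Poisson when α = 0).  Depth
    factors are log-normal(0, depth_spread) normalized to geometric
    mean 1.  Returns the count matrix and the transcript-level truth.
    """
    if config.depth_spread < 0 or (truth["effect_log2fc"] < 0).any():
        raise ValueError("negative depth spread or effect size")
    rng = config.rng(_STREAM_COUNTS)
    t2g = gpr.transcript_to_gene
    truth_by_gene = truth.set_index("gene_id")

    n = config.n_replicates
    samples = [f"{config.accession_a}_r{i + 1}" for i in range(n)] + [
        f"{config.accession_b}_r{i + 1}" for i in range(n)
    ]
    accessions = {
        s: (config.accession_a if i < n else config.accession_b)
        for i, s in enumerate(samples)
    }
    depth = np.exp(rng.normal(0.0, config.depth_spread, size=2 * n))
    depth /= np.exp(np.mean(np.log(depth)))  # geometric mean 1

    tids = t2g["transcript_id"].tolist()
    base = np.exp(
        rng.normal(np.log(config.base_mean), config.base_log_sd, size=len(tids))
    )
    calls = truth_by_gene["call"].reindex(t2g["gene_id"]).fillna("N").values
    effects = (
        truth_by_gene["effect_log2fc"].reindex(t2g["gene_id"]).fillna(0.0).values
    )
    sign = np.where(calls == "T", 1.0, np.where(calls == "S", -1.0, 0.0))
    half = 2.0 ** (sign * effects / 2.0)

    mu = np.empty((len(tids), 2 * n))
    for j in range(2 * n):
        fold = half if j < n else 1.0 / half
        mu[:, j] = base * depth[j] * fold

    if config.dispersion <= 0:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, config.dispersion * mu)
        counts = rng.poisson(lam)

    cm = CountMatrix(
        counts=pd.DataFrame(
            counts, index=pd.Index(tids, name="transcript_id"), columns=samples
        ),
        accessions=accessions,
    )
    transcript_truth = pd.DataFrame(
        {
            "transcript_id": tids,
            "gene_id": t2g["gene_id"].values,
            "call": calls,
            "effect_log2fc": sign * effects,
        }
    )
    return cm, transcript_truth


# ---------------------------------------------------------------------------
# metabolites


def default_pools() -> list[PoolDefinition]:
    """Metabolite pools linked to core-network flux groups."""
    return [
        PoolDefinition("hexose_phosphates",
                       ["G6P", "G1P", "F6P", "F16bP"], "HK_c"),
        PoolDefinition("pyruvate", ["PYR"], "PDH_m"),
        PoolDefinition("tca_intermediates",
                       ["CIT", "ICIT", "AKG", "MAL"], "TCA_m"),
        PoolDefinition("adp_glucose", ["ADPG"], "STS_p"),
        PoolDefinition("acetyl_coa", ["ACCOA"], "FAS_p"),
        PoolDefinition("erythrose_4p", ["E4P"], "PPP_p"),
        PoolDefinition("amino_acids", ["ASP", "GLU", "ALA"], "PROT_c"),
    ]


def simulate_metabolites(
    pools: list[PoolDefinition],
    config: ScenarioConfig,
    shifted: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate metabolite measurements with planted pool shifts.

    Values are log-normal around a per-compound baseline, with
    biological scatter ``bio_cv`` and technical scatter ``tech_cv``.
    ``shifted`` maps pool_id -> +1 (higher in accession A) or -1; when
    None, a seeded fraction ``metab_shift_fraction`` of pools is
    shifted by ``metab_shift_fold`` in random directions.  All members
    of a shifted pool shift together.

    Returns (measurements, truth); measurements has columns compound,
    accession, bio_rep, tech_rep, value.
    """
    rng = config.rng(_STREAM_METAB)
    if shifted is None:
        shifted = {}
        for pool in pools:
            if rng.random() < config.metab_shift_fraction:
                shifted[pool.pool_id] = 1 if rng.random() < 0.5 else -1

    sigma_bio = float(np.sqrt(np.log1p(config.bio_cv**2)))
    sigma_tech = float(np.sqrt(np.log1p(config.tech_cv**2)))
    rows = []
    for pool in pools:
        direction = shifted.get(pool.pool_id, 0)
        for member in pool.members:
            baseline = float(np.exp(rng.normal(np.log(100.0), 0.3)))
            for acc, acc_sign in (
                (config.accession_a, +1), (config.accession_b, -1)
            ):
                level = baseline * config.metab_shift_fold ** (
                    0.5 * direction * acc_sign
                )
                for b in range(1, config.n_bio_reps + 1):
                    bio = level * float(np.exp(rng.normal(0.0, sigma_bio)))
                    for t in range(1, config.n_tech_reps + 1):
                        rows.append(
                            {
                                "compound": member,
                                "accession": acc,
                                "bio_rep": b,
                                "tech_rep": t,
                                "value": bio
                                * float(np.exp(rng.normal(0.0, sigma_tech))),
                            }
                        )
    truth = pd.DataFrame(
        {
            "pool_id": [p.pool_id for p in pools],
            "shift_direction": [shifted.get(p.pool_id, 0) for p in pools],
            "shift_fold": [
                config.metab_shift_fold if p.pool_id in shifted else 1.0
                for p in pools
            ],
        }
    )
    return pd.DataFrame(rows), truth
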