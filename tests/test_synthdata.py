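"""Generators: model pair, GPR tables, planted counts, metabolites."""

import numpy as np
import pandas as pd
import pytest

from fluxcord.diffexpr import CountMatrix
from fluxcord.fva import classify_responsiveness, fba, fva
from fluxcord.metabpool import PoolDefinition, compare_pools, pool_levels
from fluxcord.synthdata import (
    GPRTables,
    ScenarioConfig,
    default_pools,
    load_core_network,
    make_gpr,
    make_model_pair,
    plant_concordance,
    simulate_counts,
    simulate_metabolites,
)

from oracles import fva_oracle


class TestConfig:
    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError, match="fractions"):
            ScenarioConfig(lipid_fraction_a=0.8, starch_fraction_a=0.5)
        with pytest.raises(ValueError, match="concordance"):
            ScenarioConfig(concordance_fraction=1.2)
        with pytest.raises(ValueError, match="dispersion"):
            ScenarioConfig(dispersion=-0.1)


class TestModelPair:
    def test_core_network_shape(self):
        m = load_core_network()
        assert 20 <= len(m.reactions) <= 40
        comps = {met.compartment for met in m.metabolites}
        assert {"c", "p", "m"} <= comps
        pathways = {r.pathway for r in m.reactions}
        assert {"sugar_uptake", "glycolysis", "pentose_phosphate", "tca",
                "fatty_acid", "starch_synthesis", "protein_synthesis",
                "transport"} <= pathways

    def test_contrasting_compositions_steer_storage_fluxes(self):
        pair = make_model_pair(ScenarioConfig(seed=0))
        fa = fba(pair.model_a)
        fb = fba(pair.model_b)
        assert fa.objective_value > 0 and fb.objective_value > 0
        # high-lipid variant makes more TAG; high-starch more starch
        assert fa.fluxes["TAG_c"] > fb.fluxes["TAG_c"] + 1e-7
        assert fb.fluxes["STS_p"] > fa.fluxes["STS_p"] + 1e-7

    def test_fva_bounds_differ_between_variants(self):
        pair = make_model_pair(ScenarioConfig(seed=0))
        ba = fva(pair.model_a, accession="A")
        bb = fva(pair.model_b, accession="B")
        diff = (ba.bounds - bb.bounds).abs().values.max()
        assert diff > 1e-7

    def test_identical_compositions_give_all_n(self):
        cfg = ScenarioConfig(
            seed=0,
            lipid_fraction_a=0.3, starch_fraction_a=0.2,
            lipid_fraction_b=0.3, starch_fraction_b=0.2,
        )
        pair = make_model_pair(cfg)
        calls = classify_responsiveness(
            fva(pair.model_a, accession="A"), fva(pair.model_b, accession="B")
        )
        assert all(c.combined == "N" for c in calls)

    def test_zero_lipid_blocks_tag_pathway(self):
        cfg = ScenarioConfig(
            seed=0,
            lipid_fraction_a=0.0, starch_fraction_a=0.3,
            lipid_fraction_b=0.0, starch_fraction_b=0.4,
        )
        pair = make_model_pair(cfg)
        for model in (pair.model_a, pair.model_b):
            bounds = fva(model).bounds
            for rid in ("TAG_c", "FAS_p", "FAT_pc"):
                assert bounds.loc[rid, "vmax"] == pytest.approx(0.0, abs=1e-6)

    def test_scaling_adds_responsive_modules(self):
        cfg = ScenarioConfig(seed=3, n_reactions=60)
        pair = make_model_pair(cfg)
        assert len(pair.model_a.reactions) >= 60
        calls = classify_responsiveness(
            fva(pair.model_a, accession="A"), fva(pair.model_b, accession="B")
        )
        responsive = [c for c in calls if c.combined in ("T", "S")]
        assert len(responsive) >= 30
        assert {c.combined for c in responsive} == {"T", "S"}


class TestGPR:
    def test_realized_transcripts_per_gene_near_target(self):
        cfg = ScenarioConfig(seed=1, n_background_genes=1000)
        gpr = make_gpr(cfg, load_core_network())
        per_gene = gpr.transcript_to_gene.groupby("gene_id").size()
        assert len(per_gene) >= 500
        assert 4.2 <= per_gene.mean() <= 5.2
        # every transcript maps to exactly one gene
        assert gpr.transcript_to_gene["transcript_id"].is_unique

    def test_single_transcript_genes_make_identity_layer(self):
        cfg = ScenarioConfig(seed=1, transcripts_per_gene_mean=1.0,
                             missing_gene_rate=0.0, n_background_genes=10)
        gpr = make_gpr(cfg, load_core_network())
        per_gene = gpr.transcript_to_gene.groupby("gene_id").size()
        assert (per_gene == 1).all()

    def test_missing_genes_flagged_and_transcriptless(self):
        cfg = ScenarioConfig(seed=2, missing_gene_rate=0.5)
        gpr = make_gpr(cfg, load_core_network())
        assert gpr.missing_genes
        with_transcripts = set(gpr.transcript_to_gene["gene_id"])
        assert not (set(gpr.missing_genes) & with_transcripts)

    def test_tsv_round_trip(self, tmp_path):
        cfg = ScenarioConfig(seed=3, n_background_genes=20)
        gpr = make_gpr(cfg, load_core_network())
        gpr.write(tmp_path / "t2g.tsv", tmp_path / "g2r.tsv")
        again = GPRTables.read(tmp_path / "t2g.tsv", tmp_path / "g2r.tsv")
        pd.testing.assert_frame_equal(again.transcript_to_gene, gpr.transcript_to_gene)
        pd.testing.assert_frame_equal(
            again.gene_to_reaction.reset_index(drop=True),
            gpr.gene_to_reaction.reset_index(drop=True),
        )
        assert again.missing_genes == gpr.missing_genes


def _flux_calls(cfg):
    pair = make_model_pair(cfg)
    return classify_responsiveness(
        fva(pair.model_a, accession="A"), fva(pair.model_b, accession="B")
    )


class TestPlantedTruth:
    def test_quota_is_exact(self):
        cfg = ScenarioConfig(seed=5, n_reactions=202)
        calls = _flux_calls(cfg)
        gpr = make_gpr(cfg, make_model_pair(cfg).model_a)
        truth = plant_concordance(calls, 0.8, gpr, cfg)
        responsive = {c.reaction_id for c in calls if c.combined in ("T", "S")}
        per_rxn = truth[truth["reaction_id"].isin(responsive)].groupby(
            "reaction_id"
        )["congruent"].first()
        # quota assignment: the congruent share among gene-bearing
        # responsive reactions sits tight around beta
        assert abs(per_rxn.mean() - 0.8) < 0.05

    @pytest.mark.parametrize("beta,expected", [(1.0, True), (0.0, False)])
    def test_extreme_betas(self, beta, expected):
        cfg = ScenarioConfig(seed=5, missing_gene_rate=0.0)
        calls = _flux_calls(cfg)
        gpr = make_gpr(cfg, make_model_pair(cfg).model_a)
        truth = plant_concordance(calls, beta, gpr, cfg)
        responsive = {c.reaction_id for c in calls if c.combined in ("T", "S")}
        planted = truth[truth["reaction_id"].isin(responsive)]
        assert (planted["congruent"] == expected).all()

    def test_beta_out_of_range(self):
        cfg = ScenarioConfig(seed=5)
        with pytest.raises(ValueError):
            plant_concordance([], 1.5, make_gpr(cfg, load_core_network()), cfg)

    def test_null_reactions_get_null_genes(self):
        cfg = ScenarioConfig(seed=5)
        calls = _flux_calls(cfg)
        gpr = make_gpr(cfg, make_model_pair(cfg).model_a)
        truth = plant_concordance(calls, 0.8, gpr, cfg)
        null_rxns = {c.reaction_id for c in calls if c.combined == "N"}
        sub = truth[truth["reaction_id"].isin(null_rxns)]
        assert (sub["call"] == "N").all()


class TestCounts:
    def _small_inputs(self, n_background_genes=50, **kw):
        cfg = ScenarioConfig(seed=7, n_background_genes=n_background_genes, **kw)
        gpr = make_gpr(cfg, load_core_network())
        truth = pd.DataFrame(
            {
                "gene_id": gpr.transcript_to_gene["gene_id"].unique(),
                "call": "N",
                "effect_log2fc": 0.0,
                "reaction_id": "",
                "congruent": False,
            }
        )
        return cfg, gpr, truth

    def test_null_truth_gives_zero_mean_log2fc(self):
        # equal depths isolate the planted (null) effect from library size
        cfg, gpr, truth = self._small_inputs(depth_spread=0.0)
        cm, _ = simulate_counts(gpr, truth, cfg)
        n = cfg.n_replicates
        mean_a = cm.counts.iloc[:, :n].mean(axis=1)
        mean_b = cm.counts.iloc[:, n:].mean(axis=1)
        keep = (mean_a > 0) & (mean_b > 0)
        lfc = np.log2(mean_a[keep] / mean_b[keep])
        assert abs(lfc.mean()) < 0.05

    def test_zero_dispersion_is_poisson(self):
        # variance/mean ratio over >= 1e4 cells approximately 1
        cfg, gpr, truth = self._small_inputs(
            n_background_genes=400, dispersion=0.0, depth_spread=0.0
        )
        cm, _ = simulate_counts(gpr, truth, cfg)
        counts = cm.counts.values
        assert counts.size >= 10_000  # simulated cells
        mean = counts.mean(axis=1)
        keep = mean > 5  # avoid ratio blow-up on near-empty rows
        ratio = (counts[keep].var(axis=1, ddof=1) / mean[keep]).mean()
        assert ratio == pytest.approx(1.0, rel=0.05)

    def test_fixed_seed_reproduces_tsv_bytes(self, tmp_path):
        cfg, gpr, truth = self._small_inputs()
        for name in ("a.tsv", "b.tsv"):
            cm, _ = simulate_counts(gpr, truth, cfg)
            cm.to_tsv(tmp_path / name)
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_planted_effect_shifts_means(self):
        cfg, gpr, truth = self._small_inputs()
        gene = truth["gene_id"].iloc[0]
        truth.loc[truth["gene_id"] == gene, ["call", "effect_log2fc"]] = ["T", 2.0]
        cm, t_truth = simulate_counts(gpr, truth, cfg)
        tids = t_truth.loc[t_truth["gene_id"] == gene, "transcript_id"]
        n = cfg.n_replicates
        sub = cm.counts.loc[tids]
        ratio = sub.iloc[:, :n].values.mean() / sub.iloc[:, n:].values.mean()
        assert 2.0 < ratio < 8.0  # close to the planted 4-fold


class TestMetabolites:
    def test_null_pools_reject_at_nominal_rate(self):
        # ~5% false positives over 1000 independent null pools
        cfg = ScenarioConfig(seed=11)
        pools = [PoolDefinition(f"p{i}", [f"c{i}"]) for i in range(1000)]
        meas, _ = simulate_metabolites(pools, cfg, shifted={})
        pooled = pool_levels(meas, pools)
        tests = compare_pools(pooled, cfg.accession_a, cfg.accession_b)
        rate = tests["significant"].mean()
        assert 0.03 <= rate <= 0.07

    def test_planted_fourfold_detected(self):
        # 500 shifted pools at 4-fold, CV 10%, n=3 -> nearly all detected
        cfg = ScenarioConfig(seed=12)
        pools = [PoolDefinition(f"p{i}", [f"c{i}"]) for i in range(500)]
        meas, truth = simulate_metabolites(
            pools, cfg, shifted={p.pool_id: 1 for p in pools}
        )
        pooled = pool_levels(meas, pools)
        tests = compare_pools(pooled, cfg.accession_a, cfg.accession_b)
        assert tests["significant"].mean() >= 0.95
        assert (tests.loc[tests["significant"], "direction"] == "A").all()

    def test_default_pools_link_to_core_reactions(self):
        model = load_core_network()
        for pool in default_pools():
            assert pool.reaction_id in model.reaction_ids

    def test_determinism(self):
        cfg = ScenarioConfig(seed=13)
        m1, t1 = simulate_metabolites(default_pools(), cfg)
        m2, t2 = simulate_metabolites(default_pools(), cfg)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(t1, t2)
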