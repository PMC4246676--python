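# Methods

## Problem and model

Two genotypes of one species are grown under identical conditions and
differ mainly in storage-product partitioning (lipid vs. starch).  For
each, flux variability analysis (FVA) of a stoichiometric model —
constrained by measured flux ratios — yields per-reaction intervals of
the optimal flux space, and RNA-seq yields a transcript × sample count
matrix (three biological replicates per accession).  The pipeline asks,
reaction by reaction, whether the direction of the flux difference
between accessions is mirrored by the direction of differential
transcription of the reaction's associated genes.

### Flux layer

FBA maximizes the biomass flux subject to steady state S·v = 0,
reaction bounds, and flux-ratio equalities v_num − r·v_den = 0.  FVA
then minimizes/maximizes each flux with the objective pinned to
`optimality_fraction` × optimum (default 1.0, i.e. the optimal face;
configurable).  LPs are solved with HiGHS via `scipy.optimize.linprog`;
feasibility tolerance 10⁻⁹, and any |v| < 10⁻⁹ is snapped to 0 before
classification so solver noise cannot masquerade as signal.

Responsiveness compares FVA bounds *by magnitude*, bound-wise (lower
with lower, upper with upper): T if |b_A| > |b_B| + ε, S the other way,
N within ε = 10⁻⁷ μmol h⁻¹.  Reversible reactions stay signed — the
absolute values implement "net flux magnitude" without splitting.  The
combined reaction call ignores N bounds; reactions whose two bounds
disagree (one T, one S) are flagged X and excluded from concordance
counts, because only unambiguous responsiveness is interpretable.  An
open design point: magnitude comparison could instead be defined over
the whole interval rather than bound-wise; bound-wise is used because
the reference worked examples report per-bound labels.

### Expression layer

The exact conditioned negative-binomial test on condition-summed counts
(the classic DESeq construction; replicate-resolved likelihood-ratio
testing is deliberately out of scope):

* size factors: median over all-positive transcripts of
  k_ij / geometric-mean_i (error with a pointer to a pseudo-reference
  fallback if no transcript is positive everywhere);
* dispersions: per-transcript method of moments on normalized counts
  pooled within accessions, α = max(0, (w − q·mean(1/s))/q²) — the
  shot-noise term is scaled by mean(1/s) because normalized counts were
  divided by the size factors — then **maximum sharing** against a
  log-log least-squares mean–dispersion trend, floored at 10⁻⁸.
  Maximum sharing (not averaging) is the choice that keeps the null
  conservative at n = 3: with 50/50 averaging the measured null
  rejection rate at p < 0.05 was ~0.085, with maximum sharing ~0.059;
* the two-sided p sums all splits (a, b) of the observed total whose
  joint probability does not exceed the observed one, normalized by the
  total over all splits.  For totals > 20 000 the summation is
  restricted to a window of ±10 conditional standard deviations around
  the mode and the observed split (omitted terms < 10⁻¹⁶ of the
  maximum; numerator and denominator share the window, so the
  truncation self-normalizes);
* NB means/dispersions for the condition sums propagate per-sample
  variances: mean q·Σs_j, dispersion α·Σs_j²/(Σs_j)²;
* both condition sums zero → p = 1 and call N; a single zero mean
  passes the fold filter and takes its p from the exact test — no
  pseudo-counts enter any call;
* Benjamini–Hochberg step-up adjustment (statsmodels);
* calls: T/S at padj < 0.01 and > 2-fold, positive direction anchored
  to the high-lipid accession.  The threshold pair is configurable; a
  stricter 4-fold (log2 ≥ 2) variant used by some visualization tools
  can be selected via `fold_threshold=4`.

The VST uses the constant-dispersion closed form with α taken from the
trend; it feeds reporting only, never calls.  log2FC is
log2(mean_high-lipid / mean_high-starch); the sign convention is forced
by the definition of "T" and surfaced here because the opposite
convention is equally common.

### Aggregation and congruence

Call combination is maximally stringent: at each level N and X are
dropped; all-T → T, all-S → S, any conflict → N, nothing left → N.
GPR boolean structure (AND/OR) is ignored — aggregation runs over the
plain associated-gene set, matching how the reference analysis treats
gene identifiers.  Gene-level "summed expression agreement" compares
per-accession sums of normalized counts with strict inequality; ties
count as disagreement.

The flux-change value is the mean of the changes of the absolute FVA
bounds; |fcv| ≥ ε defines flux-responsiveness.  Congruence pairs
(transcript p < 0.01) × (responsive reaction) score +1 iff log2FC and
fcv share a sign; an exactly-zero log2FC scores −1, since congruence is
defined only for co-signed changes.  The exported GML map nests
compartment → pathway → reaction (the minimal hierarchy), one node per
reaction id with the per-transcript congruence list (comma-joined —
GML has no list type) and a flux-direction frame attribute.

### Metabolite layer

Technical replicates are averaged before anything else (avoiding
pseudo-replication), pool values are sums of member means per
biological replicate, and accessions are compared with Welch's t-test
on biological replicates only, two-sided, p < 0.05 per pool with **no**
multiplicity correction — shifts are reported compound-wise, as in the
reference analysis, which also deliberately applies no flux–metabolite
correlation statistic (subcellular pools cannot be resolved).  Means
(not medians) over technical replicates were chosen; with ≤ 5 technical
replicates the difference is negligible and means keep pooling linear.

## Synthetic data: what it emulates

The generator produces every input under the study's design constants:
two accessions, 3 biological replicates, NB counts with dispersion
α = 0.05, log-normal library-depth spread 0.15 (normalized to geometric
mean 1 so size factors have a fixed scale), on average 4.7 transcripts
per gene (1 + Poisson(3.7), the homeolog-redundancy figure), planted
effect |log2FC| = 2, concordance fraction β = 0.8, and metabolite
replicates of 3 biological × 5 technical with CVs 0.10/0.05 and planted
4-fold pool shifts.

The toy network is a versioned JSON fixture (23 reactions, cytosol/
plastid/mitochondrion; sucrose uptake, cytosolic and plastidic
glycolysis, pentose-phosphate, TCA with a respiration overflow,
fatty-acid/TAG synthesis, starch synthesis, amino-acid/protein
synthesis, inter-compartment transporters, one flux-ratio constraint
pinning the G6P plastid import share).  Generators re-parameterize its
biomass (lipid/starch/protein fractions per accession; defaults
0.40/0.10 vs. 0.25/0.25) but never regenerate topology.  Scaling to
`n_reactions` appends 3-reaction nutrient-assimilation chains whose
biomass demand differs 1.6× between variants in a seeded direction, so
each chain is genuinely flux-responsive under FVA; ~60 modules give the
≥150 responsive reactions the recovery tests need.

Planted concordance uses quota assignment — exactly ⌊βK⌋ of the K
responsive reactions get congruent gene-level DE, the rest the opposite
direction — so recovery targets are deterministic rather than
Bernoulli-fuzzy.  Genes are generated one-reaction-each; a seeded
fraction (2%) is emitted with no transcripts to exercise the X path,
and 5% of background genes get DE in a random direction.

What the generator does *not* emulate: isoform-level expression
deconvolution, annotation error in transcript→gene mapping, GPR
boolean logic, correlated dispersion structure, batch effects, or any
coupling between flux magnitude and expression level beyond the
planted direction.  Passing recovery tests therefore show the
pipeline's bookkeeping and statistics are correct under its own model
assumptions — not that real transcript data predict flux (the
reference study's conclusion is precisely that they largely do not).

## Numerical choices and degenerate inputs

* FVA min can exceed max by solver tolerance on degenerate faces; the
  pair is re-ordered and the objective constraint is backed off by the
  LP tolerance so the optimal face stays feasible.
* Dispersion trend fitting needs ≥10 transcripts with positive raw
  estimates; otherwise the median raw estimate is used flat.
* `combine_calls` rejects unknown symbols; call-string parsing reports
  the byte position of the first invalid character.
* Metabolite comparison refuses < 2 biological replicates per side;
  zero variance on both sides gives p = 1 (equal means) or 0.
* All generators derive independent RNG streams from (seed, stream-id)
  pairs, so adding a generator never perturbs another's draws.

## Problem sizes used in the checks

The acceptance-style checks run at desk scale: the 27-row fixture for
the exact counts; 4 toy models (≤5 reactions) against the
vertex-enumeration oracle; 5 000 null transcripts for test calibration;
202-reaction synthetic scenarios (~6 000 transcripts, ~1 300 genes) for
three-seed recovery of β.  These sizes were chosen as the smallest at
which the statistical bands are tight enough to be meaningful.

## Known limitations

* The exact test inherits DESeq-classic behavior: conservative at small
  n, and no shrunken fold changes.
* Bound-wise magnitude comparison can differ from interval-based
  definitions for reactions whose interval spans zero asymmetrically.
* The GML export is a compatibility artifact (node/attribute
  conventions for hierarchical pathway maps), not an interactive
  visualization.
* SBML import covers Level-3 core + FBC bounds/objective with flattened
  gene associations; kinetic laws, compartments sizes and annotations
  are ignored.
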