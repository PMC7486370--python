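# Methods

This note documents the models behind each pipeline stage, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Synthetic study design

The generator (`mucoseq.synth`) emulates a within-subject gut biogeography
study: `n_subjects = 5`, each contributing biopsies from terminal ileum
(TI), transverse colon (TC) and rectum (RE) plus a faecal sample (FE); one
subject's ileum is unreachable and a caecum (CA) biopsy substitutes
(`ca_subject = 0`). TI and CA are pooled as TI\* in all location-level
summaries; the raw CA sample stays accessible.

**Abundance model.** True MGS profiles are log-normal fields passed through
a softmax per sample:

    log a(m, s) = baseline(m) + subject(subj(s), m) + location(loc(s), m)
                  + spikes + noise(s, m)

with one standard deviation per tier: `baseline_sd = 2.0` (a steep
rank-abundance curve — a handful of dominant species over a long rare
tail), `subject_effect_sd = 1.5`, `location_effect_sd = 0.5`,
`noise_sd = 0.3`. The invariant `subject_effect_sd > location_effect_sd`
encodes the study's central observation: biopsy samples cluster by
individual, not by gut segment. Faecal samples have their log-field
multiplied by `faecal_flatten = 0.5` before spiking: faecal communities are
far more even than mucosal ones, which is what keeps them richer *after*
joint rarefaction equalises read depth. Two genus spikes set the
compartment signature: the Bacteroides-like genus +2 log units in all
biopsies (the dominant discriminator) and the Bifidobacterium-like genus
+1 log unit in faeces (real but weaker — strong enough to show up in the
genus scatter, weak enough that removing Bacteroides alone restores the
biopsy–faeces correlation).

**Read model.** Depths default to 500 000 reads per biopsy with a host
fraction of 0.97 (so 15 000 microbial reads) and 580 000 per faecal sample
with no host reads — roughly the 40-fold microbial-yield gap between the
two sample types, at desk scale. Gene-level expected counts are
proportional to MGS abundance × gene length (lengths ~ lognormal, median
1 kb); counts are multinomial. A `multimap_fraction = 0.10` of each gene's
reads is re-emitted as shared groups over the gene's within-MGS homolog
family (consecutive chunks of 2–5 genes), making occurrence normalisation
consequential; unique + shared read totals equal the drawn microbial depth
exactly. ARG covered fractions come from a two-component Beta mixture —
Beta(40, 2) high-coverage and Beta(2, 4) low-coverage, with the
high-coverage weight rising with read count — so the 90% coverage filter
is genuinely selective. All randomness flows from a single integer seed.

**What the generator does not emulate:** read-level sequences and errors,
host sequence, strain-level variation within an MGS, compositional
sequencing artefacts, chimeric multi-mapping across MGSs, and longitudinal
dynamics. Tests passing on this generator show the pipeline's operations
are correct and recover planted structure; they do not certify effect
sizes on real cohorts.

## Quantification

Shared (multi-mapped) read groups are split over their k target genes —
`equal` policy 1/k by default, or `weighted` by the member genes' unique
counts (both conserve total read mass to 1e−9; the field's tools differ
here, so both are exposed). Rarefaction is sampling without replacement
(multivariate hypergeometric), the standard model of downsizing a read
pool; real-valued columns (after shared-read splitting) are first rounded
by a largest-remainder rule that preserves totals. The default target depth
is the minimum column total of the jointly normalised set, i.e. biopsies
and faeces are downsized together. Length normalisation is reads per
kilobase. Detection for richness is strictly abundance > 0 after
rarefaction (configurable threshold).

## MGS profiling and biogeography

An MGS abundance is the mean over its 50 centroid genes; centroid genes
missing from a matrix contribute 0 but stay in the denominator, keeping
profiles comparable across samples. Shared-MGS percentages are reported in
two modes, `jaccard` (|A∩B|/|A∪B|) and `of_a` (|A∩B|/|A|), because the
one-sided and union-based readings are both defensible; neither is
suppressed. Taxon aggregation is a group-by sum over the MGS taxonomy at
phylum/class/genus/species rank and conserves per-sample totals.

## Ordination and statistics

PCoA is classical (Torgerson) scaling of −D²/2: double-centre,
eigendecompose, scale eigenvectors by √λ. Bray–Curtis is a semimetric, so
negative eigenvalues occur; they are reported (as a negative-inertia
fraction) and their axes dropped — no Cailliez correction. Bray–Curtis on
relative abundances is the default ordination metric; the choice is a
package default, not a claim about any particular study's metric.

"R" values are Spearman ρ (rank correlation of group-mean abundances over
features detected in both groups, midrank ties); "R²" is squared Pearson on
untransformed group means. Both are reported side by side because the two
conventions coexist in the literature.

The Wilcoxon signed-rank test drops zero differences (Wilcoxon's rule),
midranks ties, and computes the exact two-sided p for n ≤ 25 informative
pairs by dynamic programming over the 2ⁿ sign assignments (doubling ranks
to keep sums integral); beyond that a normal approximation with tie
correction applies. Two-sided p is the null mass at or beyond the observed
statistic on both tails, which matches full enumeration and scipy's exact
mode on tie-free data. With the study's n = 5 subjects the smallest
attainable two-sided p is 2/2⁵ = 0.0625 — paired tests at this scale can
flag only the most extreme orderings, which the power-sensitive recovery
tests acknowledge by simulating larger synthetic cohorts (n = 10).

## Resistome

An ARG is retained in a sample iff its covered fraction is ≥ 0.90 (the
boundary survives; "below 90%" is discarded) *and* it has mapped reads;
the filter is per-sample and idempotent. Normalisation is DESeq2's
median-of-ratios: factors are medians (taken in ratio space) of
count/geometric-mean over ARGs positive in every sample; with sparse
filtered matrices, where no ARG is shared by all samples, a `poscounts`
pseudo-reference (geometric means over positive entries, medians over each
sample's detected ARGs) is used automatically. Note the true invariances:
identical columns give unit factors, column j = c × column k implies
factor_j = c·factor_k within a matrix, and rescaling the *whole* matrix
leaves factors unchanged (the scaling cancels against the reference).

Differential enrichment aggregates normalised counts to drug-class or
mechanism level (multi-label ARGs count once per label, CARD's convention;
a `unique_class` switch restricts to single-label ARGs when conservation
matters), then tests each feature per location with a paired exact
Wilcoxon of the subject's value at that location against the subject's
mean elsewhere, BH-corrected across features within each contrast. A
negative-binomial Wald test is deliberately not used: with five subjects
per group, dispersion estimation is the fragile step, and the questions
asked of the resistome here are directional.

## Pathway enrichment

Presence/absence over-representation: for a location, the detected KO set
is the union over genes with abundance > 0 in any of its samples; each
pathway gets a one-sided hypergeometric p for its overlap with the
detected set against the full annotated-catalogue background (the
`detected_any` background is available as an option). Raw p < 0.05 drives
the `significant` flag — the uncorrected convention — with BH q reported
alongside, never suppressed. Contributing species are MGSs ranked by the
summed location-mean abundance of their genes annotated to the pathway's
KOs; contribution fractions sum to 1.

## Genome-scale metabolic modelling

The universal reaction database is an explicit, versioned fixture
(39 metabolites, 50 reactions): a glycolysis-like backbone (net 2 ATP per
hexose), fermentation branches to acetate, propionate, butyrate, formate,
lactate, ethanol and succinate, tryptophanase
(Trp → indole + pyruvate + NH₃), amino-acid uptake routes, optional O₂
respiration (5 ATP per pyruvate), and a biomass drain consuming pyruvate,
acetyl-CoA and ATP. The JSON schema accepts genome-scale databases
drop-in. Exchange fluxes are signed positive = secretion; diet uptake
limits (mmol/gDW/h) set exchange lower bounds to −rate, unlisted
metabolites are closed.

**FBA** maximises biomass with HiGHS LP; every returned solution is
verified against S·v = 0 (1e−6) and bounds (1e−9). Because LP optima are
degenerate, reported flux profiles are made deterministic by a
lexicographic second stage: fix the biomass optimum, minimise Σ|v|
(split-variable LP). **Gap filling** searches candidate sets by ascending
cardinality, exhaustively (hence certified minimal, ties broken
lexicographically by reaction id) when at most 12 candidate reactions are
missing; larger universes use a deterministic add-all-then-prune pass
(pruning from the highest reaction id, so low ids are preferentially
retained).

**Community simulation** is two-phase. Phase 1 solves each species
anaerobically under the diet; the across-species arithmetic mean of
acetate and lactate secretion is added to the shared medium as extra
uptake allowance (cross-feeding seed). Phase 2 re-solves each species with
biomass fixed (equality) to its phase-1 growth scaled by its location
relative abundance, under the augmented diet, minimising total flux; if
that is infeasible the biomass constraint relaxes to ≥ 95% of target, and
the relaxation is logged. Location summaries weight species exchange
fluxes linearly by relative abundance — there is no shared-metabolite
competition LP, by design. Exchange-set similarity is Jaccard over signed
(metabolite, direction) pairs with activity threshold |v| > 1e−6; two
fully inactive profiles are defined as similarity 1.

**Oxygen sweeps** bound O₂ uptake at f × reference for a grid of fractions
including 0 (anaerobic — literally the same LP as the anaerobic solve) and
0.05 (micro-aerobic). The tissue-level reference, 2 mL O₂/min per 100 g,
is converted once by a named constant: 22.4 mL/mmol (ideal gas), 60 min/h,
and an assumed 1 g dry-weight microbial biomass per 100 g tissue, giving
5.36 mmol/gDW/h; each of those assumptions is visible and overridable in
`OxygenSweepConfig`. A species' oxygen sensitivity is summarised as
growth(0)/growth(0.05).

The packaged community fixture holds four species with disjoint
fermentation endpoints — a dominant acetate producer, a propionate
producer, a rectum-enriched butyrate producer, and a sugar-free tryptophan
fermenter present only in TI\*/TC. The fixture's abundances make the
weighted secretion ordering acetate > propionate > butyrate hold at every
location, and force indole (1:1 with tryptophanase flux) to localise with
its carrier: because phase 2 minimises total flux, a species with a
cheaper sugar route would never touch tryptophan, so the carrier is built
as an amino-acid fermenter.

## Problem sizes and tolerances

Test and script workloads are scaled so the whole suite runs in well under
a minute of CPU: recovery tests use 8–15 MGS worlds at 40–200 k reads per
sample over up to 20 seeds; the acceptance script runs the full default
conditions (100 MGSs × 120 genes, 500–580 k reads per sample) once.
Multi-seed recovery assertions are majority- or 90%-of-seeds criteria,
matching the stochastic nature of the planted effects. Oracle comparisons
use 1e−6 for LP optima, 1e−9 for mass conservation, exact equality for
rarefaction column sums and the anaerobic/f = 0 identity, and 1e−12-scale
agreement for the exact combinatorial tests.

## Known limitations

Equal 1/k shared-read splitting and the catalogue-wide enrichment
background are conventions, not inferences; MGS discovery (co-abundance
clustering) is out of scope — clusters arrive as input; the reaction
universe is a fermentation cartoon whose fluxes are qualitatively, not
quantitatively, comparable to genome-scale reconstructions; the community
model has no metabolite competition, so secretion totals scale linearly
with abundance by construction; and exact Wilcoxon at n = 5 cannot reach
p < 0.0625, which bounds what any paired analysis of a five-subject design
can call significant.
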