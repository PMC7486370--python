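# mucoseq

Biogeography of the gut mucosal microbiome, as a tested analysis pipeline on
synthetic shotgun-metagenomics data.

Faecal metagenomics sees an averaged picture of the gut; mucosal biopsies
from terminal ileum (TI, or caecum CA when the ileum is unreachable),
transverse colon (TC) and rectum (RE) see the local communities — but at a
price: ~97% of biopsy reads are host DNA, so the microbial signal is
shallow. `mucoseq` implements the full analysis chain used to compare these
compartments, together with a synthetic-data generator that emulates the
study design (5 subjects × {TI/CA, TC, RE, FE}), so that every stage is
testable without access to raw sequencing data:

1. **Quantification** — gene counts from alignment summaries: unique reads
   plus multi-mapped read groups split over their *k* target genes
   (count(g) = unique(g) + Σ group/k), joint rarefaction to a common depth
   by multivariate hypergeometric subsampling, reads-per-kilobase length
   normalisation.
2. **MGS profiling** — a metagenomic species (MGS) is a cluster of >100
   co-abundant genes quantified as the mean abundance of its 50 centroid
   genes; richness, shared-MGS percentages and subject-sharing statistics.
3. **Diversity & biogeography** — Bray–Curtis dissimilarity
   BC(i,j) = 1 − 2Σmin(xᵢ,xⱼ)/(Σxᵢ+Σxⱼ), classical-scaling PCoA, genus-level
   Spearman ρ and Pearson r² between compartments, and an exact paired
   Wilcoxon signed-rank test (full null enumeration up to n = 25).
4. **Resistome** — CARD-style ARG annotation, per-sample discard of ARGs
   with read coverage below 90%, DESeq2 median-of-ratios size factors
   sⱼ = medianᵢ kᵢⱼ/(∏ⱼkᵢⱼ)^(1/m), and location enrichment of drug classes
   and resistance mechanisms (paired exact Wilcoxon + Benjamini–Hochberg).
5. **Pathway enrichment** — one-sided hypergeometric over-representation of
   each KEGG pathway among the KOs detected at a location, with the MGSs
   driving each enrichment ranked by abundance-weighted contribution.
6. **Community metabolic modelling** — draft genome-scale models built from
   KO sets against a universal reaction database, minimal-cardinality gap
   filling, diet-constrained anaerobic FBA (max biomass s.t. S·v = 0,
   lb ≤ v ≤ ub), a two-phase community simulation with acetate/lactate
   cross-feeding and abundance-weighted secretion per gut location,
   exchange-set Jaccard similarity, and oxygen-sensitivity sweeps against
   the intestinal O₂ reference uptake (micro-aerobic = 5%).

## Worked example

```python
from mucoseq.synth import GeneratorConfig, generate_world, generate_read_counts
from mucoseq.workflow import world_pipeline
from mucoseq.mgs import mgs_richness, shared_mgs_percentage
from mucoseq.diversity import genus_scatter_r2
from mucoseq.gem import community_fixture, community_simulate, trp_indole_report

cfg = GeneratorConfig(seed=1)                 # the default study conditions
world = generate_world(cfg)
reads = generate_read_counts(world, cfg)
res = world_pipeline(world, reads, seed=2)    # resolve, rarefy, normalise

loc = world.metadata.table["location"]
rich = mgs_richness(res.mgs_profile)
print(f"rarefaction depth: {res.target_depth} reads/sample")
print(f"mean MGS richness  biopsies: {rich[loc != 'FE'].mean():.1f}   "
      f"faeces: {rich[loc == 'FE'].mean():.1f}")
rep_all, rep_excl = genus_scatter_r2(res.genus_relative, world.metadata,
                                     "biopsy", "FE", exclude=["Bacteroides"])
print(f"genus scatter r2: {rep_all.pearson_r2:.2f} -> "
      f"{rep_excl.pearson_r2:.2f} after excluding Bacteroides")

models, abundances, diet = community_fixture()
com = community_simulate(models, abundances, diet)
w = com["TI*"].weighted_exchange
print(f"TI* secretion: acetate {w['ac_e']:.3f}, propionate {w['ppa_e']:.3f}, "
      f"butyrate {w['but_e']:.3f} mmol/gDW/h")
print(trp_indole_report(com).round(3))
```

Output:

```
rarefaction depth: 15000 reads/sample
mean MGS richness  biopsies: 64.4   faeces: 99.8
genus scatter r2: 0.43 -> 0.89 after excluding Bacteroides
TI* secretion: acetate 0.910, propionate 0.114, butyrate 0.005 mmol/gDW/h
          trp_uptake  indole_secretion  tryptophanase_flux
location
RE              0.00              0.00                0.00
TC              0.08              0.08                0.08
TI*             0.08              0.08                0.08
```

Reading it: after joint downsizing, faecal samples still detect more
species than the shallow, host-dominated biopsies; the biopsy-enriched
*Bacteroides*-like genus is the outlier that depresses the faeces-vs-biopsy
genus correlation, and removing it restores the fit. In the community
models, weighted SCFA secretion is ordered acetate > propionate > butyrate
at every location, and indole (1:1 with tryptophanase flux) is produced
only where the tryptophan-fermenting species lives (TI*, TC) — the rectum
community, which lacks the carrier, secretes none.

A thin CLI mirrors the stages: `mucoseq simulate`, `mucoseq quantify`,
`mucoseq biogeography`, `mucoseq ordinate`, `mucoseq resistome`,
`mucoseq gapfill` (see `--help`).

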