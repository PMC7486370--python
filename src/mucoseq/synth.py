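"""Synthetic mucosal/faecal metagenome generator.

Emulates the data model of a 5-subject gut biogeography study: per-subject
biopsy samples from terminal ileum (TI, or caecum CA for one subject),
transverse colon (TC) and rectum (RE), plus a faecal sample (FE). The
generator produces a gene catalogue organised into metagenomic species
(MGS), log-normal community profiles in which subject identity explains
more variance than sampling location, genus spikes (a Bacteroides-like
genus enriched in biopsies, a Bifidobacterium-like genus in faeces), read
counts with heavy host contamination in biopsies (~97% of biopsy reads are
host and never reach the catalogue), multi-mapped read groups drawn within
MGS homolog families, ARG annotations with CARD-style drug classes and
mechanisms, and the reaction universe + diet used by the metabolic
modelling stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import KOAnnotation
from .gem import DietConstraint, UniversalReactionDB, default_diet, fermentation_universe
from .mgs import BIOPSY_LOCATIONS, LOCATIONS, MGS, MGSSet, SampleMetadata
from .quantify import AlignmentSummary
from .resistome import ARGRecord, MECHANISMS

__all__ = [
    "GeneratorConfig", "SyntheticWorld", "generate_world",
    "generate_read_counts", "species_ko_set", "GENUS_TAXONOMY", "PATHWAYS",
]

#: genus -> (phylum, class); a small realistic gut roster
GENUS_TAXONOMY: dict[str, tuple[str, str]] = {
    "Bacteroides": ("Bacteroidetes", "Bacteroidia"),
    "Prevotella": ("Bacteroidetes", "Bacteroidia"),
    "Parabacteroides": ("Bacteroidetes", "Bacteroidia"),
    "Bifidobacterium": ("Actinobacteria", "Actinobacteria"),
    "Collinsella": ("Actinobacteria", "Coriobacteriia"),
    "Faecalibacterium": ("Firmicutes", "Clostridia"),
    "Ruminococcus": ("Firmicutes", "Clostridia"),
    "Eubacterium": ("Firmicutes", "Clostridia"),
    "Blautia": ("Firmicutes", "Clostridia"),
    "Roseburia": ("Firmicutes", "Clostridia"),
    "Anaerostipes": ("Firmicutes", "Clostridia"),
    "Lactobacillus": ("Firmicutes", "Bacilli"),
    "Streptococcus": ("Firmicutes", "Bacilli"),
    "Akkermansia": ("Verrucomicrobia", "Verrucomicrobiae"),
    "Escherichia": ("Proteobacteria", "Gammaproteobacteria"),
}

#: KEGG-style pathway map used for enrichment fixtures
PATHWAYS: dict[str, tuple[str, tuple[str, ...]]] = {
    "ko00010": ("Glycolysis / Gluconeogenesis",
                ("K00844", "K00849", "K01810", "K00016", "K00925")),
    "ko00190": ("Oxidative phosphorylation",
                ("K02274", "K02275", "K02276", "K00404")),
    "ko00906": ("Carotenoid biosynthesis",
                ("K02291", "K10027", "K09844", "K06443")),
    "ko00380": ("Tryptophan metabolism", ("K01667", "K03835", "K05802")),
    "ko00650": ("Butanoate metabolism", ("K00248", "K00656")),
}

_CORE_KOS = ("K00844", "K01810", "K00925", "K00656", "K02777", "K21990",
             "K03320", "K06287", "K06188")
_GENUS_KOS: dict[str, tuple[str, ...]] = {
    "Bacteroides": ("K01667", "K03835", "K05802", "K01026", "K03291",
                    "K03290", "K02274", "K02275"),
    "Prevotella": ("K01026", "K03291", "K03290"),
    "Parabacteroides": ("K02291", "K10027", "K03290", "K01026", "K03291"),
    "Bifidobacterium": ("K02773", "K00849", "K00016", "K03303", "K03290"),
    "Collinsella": ("K00016", "K03303"),
    "Faecalibacterium": ("K00248", "K03292", "K02291", "K09844", "K03290"),
    "Ruminococcus": ("K00248", "K03292", "K03290"),
    "Eubacterium": ("K00248", "K03292", "K03290"),
    "Blautia": ("K03290", "K01895"),
    "Roseburia": ("K00248", "K03292", "K03290"),
    "Anaerostipes": ("K00248", "K03292", "K00016", "K03303"),
    "Lactobacillus": ("K00016", "K03303"),
    "Streptococcus": ("K00016", "K03303", "K02274", "K02441"),
    "Akkermansia": ("K02291", "K10027", "K06443", "K03290", "K00261",
                    "K10005"),
    "Escherichia": ("K02274", "K02276", "K00404", "K02441", "K01667",
                    "K03835", "K05802", "K04072", "K03299"),
}

_DRUG_CLASSES = ("cephamycin", "tetracycline antibiotic",
                 "fluoroquinolone antibiotic", "glycopeptide antibiotic",
                 "penam", "macrolide antibiotic")


def species_ko_set(genus: str) -> frozenset[str]:
    """Functional KO repertoire of a genus (core fermentation + extras)."""
    if genus not in GENUS_TAXONOMY:
        raise KeyError(f"unknown genus {genus!r}")
    return frozenset(_CORE_KOS) | frozenset(_GENUS_KOS.get(genus, ()))


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cohort.

    Defaults mirror the scale of the emulated study: 5 subjects, three
    biopsy locations plus faeces (one subject contributes CA instead of TI),
    97% host reads in biopsies, and roughly a 40-fold gap between faecal and
    biopsy microbial read yield. Subject variance exceeds location variance,
    so samples cluster by individual rather than by gut segment.
    """

    n_subjects: int = 5
    locations: tuple[str, ...] = ("TI", "TC", "RE", "FE")
    ca_subject: int | None = 0   # subject index sampling CA instead of TI
    n_mgs: int = 100
    genes_per_mgs: int = 120
    n_centroids: int = 50
    host_read_fraction_biopsy: float = 0.97
    depth_faeces: int = 580_000
    depth_biopsy: int = 500_000
    baseline_sd: float = 2.0
    # steep log-normal rank-abundance: a handful of dominant species and a
    # long rare tail, as in real gut communities
    faecal_flatten: float = 0.5
    # log-field multiplier for FE samples (< 1 flattens the community:
    # faecal microbiota are far more even, hence richer at equal depth)
    subject_effect_sd: float = 1.5
    location_effect_sd: float = 0.5
    noise_sd: float = 0.3
    # Bacteroides is THE biopsy discriminator; the faecal Bifidobacterium
    # enrichment is real but weaker
    spike_config: tuple[tuple[str, str, float], ...] = (
        ("Bacteroides", "biopsy", 2.0),
        ("Bifidobacterium", "FE", 1.0),
    )
    arg_genes_per_mgs: int = 2
    arg_mechanism_spikes: tuple[tuple[str, str], ...] = ()
    # (mechanism, genus): ARGs carried by that genus get that mechanism
    multimap_fraction: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.genes_per_mgs <= 100:
            raise ValueError("genes_per_mgs must exceed 100 "
                             "(an MGS has more than 100 genes)")
        if self.n_centroids > self.genes_per_mgs:
            raise ValueError("n_centroids cannot exceed genes_per_mgs")
        if self.n_centroids < 1 or self.n_mgs < 1 or self.n_subjects < 1:
            raise ValueError("n_centroids, n_mgs and n_subjects must be >= 1")
        if self.faecal_flatten < 0:
            raise ValueError("faecal_flatten must be non-negative")
        for name in ("host_read_fraction_biopsy", "multimap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.subject_effect_sd <= self.location_effect_sd and not (
                self.subject_effect_sd == self.location_effect_sd == 0.0):
            raise ValueError(
                "subject_effect_sd must exceed location_effect_sd "
                "(individual uniqueness dominates location)")
        if any(sd < 0 for sd in (self.baseline_sd, self.subject_effect_sd,
                                 self.location_effect_sd, self.noise_sd)):
            raise ValueError("effect SDs must be non-negative")
        bad = set(self.locations) - set(LOCATIONS)
        if bad:
            raise ValueError(f"unknown location code(s): {sorted(bad)}")
        for mech, genus in self.arg_mechanism_spikes:
            if mech not in MECHANISMS:
                raise ValueError(f"unknown resistance mechanism {mech!r}")


@dataclass
class SyntheticWorld:
    catalogue: pd.DataFrame          # one row per gene
    mgs_set: MGSSet
    true_profiles: pd.DataFrame      # MGS x sample relative abundances
    metadata: SampleMetadata
    annotation: KOAnnotation
    arg_records: list[ARGRecord]
    homolog_families: dict[str, tuple[str, ...]]  # gene -> its family
    reaction_universe: UniversalReactionDB
    diet: DietConstraint

    @property
    def gene_lengths(self) -> pd.Series:
        return self.catalogue.set_index("gene_id")["length_bp"]


def _sample_table(config: GeneratorConfig) -> pd.DataFrame:
    rows = {}
    for i in range(config.n_subjects):
        subj = f"S{i + 1}"
        for loc in config.locations:
            eff = loc
            if loc == "TI" and config.ca_subject == i:
                eff = "CA"
            rows[f"{subj}_{eff}"] = {"subject_id": subj, "location": eff}
    return pd.DataFrame(rows).T


def _resolve_group(label: str, locations: pd.Series) -> pd.Series:
    if label == "biopsy":
        return locations.isin(BIOPSY_LOCATIONS)
    if label == "TI*":
        return locations.isin(["TI", "CA"])
    if label in ("faeces", "FE"):
        return locations == "FE"
    if label in LOCATIONS:
        return locations == label
    raise ValueError(f"unknown spike target group {label!r}")


def generate_world(config: GeneratorConfig) -> SyntheticWorld:
    """Build the full synthetic study (deterministic given config.seed).

    True MGS profiles are softmax-normalised log-normal fields:
    baseline + subject effect + location effect + genus spikes + noise.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])

    genera = list(GENUS_TAXONOMY)
    mgs_rows, cat_rows, mgs_list = [], [], []
    gene_kos: dict[str, frozenset[str]] = {}
    arg_records: list[ARGRecord] = []
    homolog: dict[str, tuple[str, ...]] = {}
    for m in range(config.n_mgs):
        mgs_id = f"MGS{m + 1:04d}"
        genus = genera[m % len(genera)]
        phylum, klass = GENUS_TAXONOMY[genus]
        taxonomy = {"phylum": phylum, "class": klass, "genus": genus,
                    "species": f"{genus} sp. {mgs_id}"}
        genes = [f"{mgs_id}_g{j + 1:04d}" for j in range(config.genes_per_mgs)]
        lengths = np.clip(rng.lognormal(np.log(1000), 0.35,
                                        size=len(genes)), 300, 6000).astype(int)
        # KO assignment: the genus repertoire spread over the first genes,
        # two carrier genes per KO
        repertoire = sorted(species_ko_set(genus))
        for j, g in enumerate(genes):
            kos = []
            if j < 2 * len(repertoire):
                kos.append(repertoire[j % len(repertoire)])
            if kos:
                gene_kos[g] = frozenset(kos)
        # ARG annotation on the last genes of the cluster
        spiked_mechs = [mech for mech, gn in config.arg_mechanism_spikes
                        if gn == genus]
        for a in range(config.arg_genes_per_mgs):
            g = genes[-(a + 1)]
            arg_id = f"ARG_{mgs_id}_{a + 1}"
            n_classes = 1 + int(rng.random() < 0.25)
            classes = rng.choice(_DRUG_CLASSES, size=n_classes, replace=False)
            if spiked_mechs:
                mechs = list(spiked_mechs)
            else:
                base = [m_ for m_ in MECHANISMS
                        if m_ != "Antibiotic target replacement"]
                mechs = [base[int(rng.integers(len(base)))]]
            arg_records.append(ARGRecord(arg_id, g, frozenset(classes),
                                         frozenset(mechs)))
        # homolog families: consecutive chunks of 2-5 genes
        j = 0
        while j < len(genes):
            size = int(rng.integers(2, 6))
            fam = genes[j: j + size]
            if len(fam) == 1:  # tail singleton joins the previous family
                prev = homolog[genes[j - 1]]
                fam = list(prev) + fam
                for g in fam:
                    homolog[g] = tuple(fam)
                break
            for g in fam:
                homolog[g] = tuple(fam)
            j += size
        arg_by_gene = {r.gene_id: r for r in arg_records}
        for g, L in zip(genes, lengths):
            rec = arg_by_gene.get(g)
            cat_rows.append({
                "gene_id": g, "length_bp": int(L), "mgs_id": mgs_id,
                "phylum": phylum, "class": klass, "genus": genus,
                "species": taxonomy["species"],
                "ko_ids": ";".join(sorted(gene_kos.get(g, ()))),
                "arg_id": rec.arg_id if rec else "",
                "drug_classes": ";".join(sorted(rec.drug_classes)) if rec else "",
                "mechanisms": ";".join(sorted(rec.mechanisms)) if rec else "",
            })
        centroids = tuple(genes[: config.n_centroids])
        mgs_list.append(MGS(mgs_id, frozenset(genes), centroids, taxonomy))
        mgs_rows.append(mgs_id)

    catalogue = pd.DataFrame(cat_rows)
    mgs_set = MGSSet(mgs_list)
    meta_table = _sample_table(config)
    metadata = SampleMetadata(meta_table)
    samples = list(meta_table.index)
    locations = meta_table["location"]
    subjects = sorted(set(meta_table["subject_id"]))

    n_m = config.n_mgs
    baseline = rng.normal(0.0, config.baseline_sd, size=n_m)
    subj_eff = {s: rng.normal(0.0, config.subject_effect_sd, size=n_m)
                for s in subjects}
    loc_eff = {loc: rng.normal(0.0, config.location_effect_sd, size=n_m)
               for loc in LOCATIONS}
    genus_of = np.array([m_.taxonomy["genus"] for m_ in mgs_list])

    log_abund = {}
    for s in samples:
        subj, loc = meta_table.loc[s, "subject_id"], meta_table.loc[s, "location"]
        la = baseline + subj_eff[subj] + loc_eff[loc]
        la = la + rng.normal(0.0, config.noise_sd, size=n_m)
        if loc == "FE":
            la = la * config.faecal_flatten
        for genus, group, lfc in config.spike_config:
            if _resolve_group(group, locations)[s]:
                la = la + np.where(genus_of == genus, lfc, 0.0)
        log_abund[s] = la
    la_df = pd.DataFrame(log_abund, index=mgs_rows)
    profiles = np.exp(la_df - la_df.max(axis=0))
    profiles = profiles / profiles.sum(axis=0)

    ko_pathways = {}
    for pid, (_, kos) in PATHWAYS.items():
        for k in kos:
            ko_pathways.setdefault(k, set()).add(pid)
    annotation = KOAnnotation(
        gene_kos=gene_kos,
        ko_pathways={k: frozenset(v) for k, v in ko_pathways.items()},
        pathway_names={pid: name for pid, (name, _) in PATHWAYS.items()},
    )

    return SyntheticWorld(
        catalogue=catalogue, mgs_set=mgs_set, true_profiles=profiles,
        metadata=metadata, annotation=annotation, arg_records=arg_records,
        homolog_families=homolog, reaction_universe=fermentation_universe(),
        diet=default_diet(),
    )


def _coverage(count: int, rng: np.random.Generator) -> float:
    """Covered fraction from a two-component Beta mixture.

    The high-coverage component Beta(40, 2) dominates for well-sampled
    genes; shallowly sampled genes mostly draw from the low component
    Beta(2, 4), which makes a 90% coverage filter genuinely selective.
    """
    if count <= 0:
        return 0.0
    p_high = 1.0 - 0.9 * np.exp(-count / 4.0)
    if rng.random() < p_high:
        return float(rng.beta(40, 2))
    return float(rng.beta(2, 4))


def generate_read_counts(world: SyntheticWorld, config: GeneratorConfig
                         ) -> dict[str, AlignmentSummary]:
    """Simulate per-sample alignment summaries from the true profiles.

    Microbial read depth is depth x (1 - host fraction) for biopsies and the
    full faecal depth for FE. Expected gene counts are proportional to the
    gene's MGS abundance times gene length; a ``multimap_fraction`` of each
    gene's reads is emitted as shared groups over its within-MGS homolog
    family. Unique + shared totals equal the microbial depth exactly.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    cat = world.catalogue
    genes = cat["gene_id"].to_numpy()
    lengths = cat["length_bp"].to_numpy(dtype=float)
    mgs_of = cat["mgs_id"].to_numpy()
    out: dict[str, AlignmentSummary] = {}
    arg_genes = {r.gene_id for r in world.arg_records}
    for s in world.true_profiles.columns:
        loc = world.metadata.table.loc[s, "location"]
        is_biopsy = loc in BIOPSY_LOCATIONS
        depth = config.depth_biopsy if is_biopsy else config.depth_faeces
        host = config.host_read_fraction_biopsy if is_biopsy else 0.0
        microbial = int(round(depth * (1.0 - host)))
        w = world.true_profiles[s].reindex(mgs_of).to_numpy() * lengths
        w = w / w.sum()
        counts = rng.multinomial(microbial, w)
        shared_part = rng.binomial(counts, config.multimap_fraction)
        unique = counts - shared_part
        shared_groups: dict[frozenset[str], int] = {}
        for g, c in zip(genes[shared_part > 0], shared_part[shared_part > 0]):
            fam = frozenset(world.homolog_families[g])
            shared_groups[fam] = shared_groups.get(fam, 0) + int(c)
        # Lander-Waterman-style expected coverage for 100 bp reads
        lw = 1.0 - np.exp(-counts * 100.0 / lengths)
        covered = {g: float(v) for g, v in zip(genes[counts > 0],
                                               lw[counts > 0])}
        for g, c in zip(genes, counts):
            if g in arg_genes:
                covered[g] = _coverage(int(c), rng)
        covered = {g: v for g, v in covered.items() if v > 0}
        out[s] = AlignmentSummary(
            sample_id=s,
            unique_counts={g: int(c) for g, c in zip(genes, unique) if c > 0},
            shared_groups=sorted(shared_groups.items(),
                                 key=lambda kv: sorted(kv[0])),
            covered_fraction=covered,
        )
    return out
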