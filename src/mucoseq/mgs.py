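"""Metagenomic-species (MGS) profiling and biogeography summaries.

An MGS is a cluster of > 100 co-abundant catalogue genes treated as one
species-level unit; its abundance in a sample is the mean abundance of its 50
designated centroid genes. This module turns gene-level abundance tables into
MGS and taxon tables and computes the sharing statistics used to compare gut
locations (terminal ileum TI, caecum CA, transverse colon TC, rectum RE) and
faeces (FE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import AbundanceMatrix

__all__ = [
    "MGS",
    "MGSSet",
    "SampleMetadata",
    "LOCATIONS",
    "BIOPSY_LOCATIONS",
    "profile_mgs",
    "mgs_richness",
    "shared_mgs_percentage",
    "subject_sharing_percentage",
    "aggregate_taxa",
    "top_taxa",
]

LOCATIONS = ("TI", "CA", "TC", "RE", "FE")
#: biopsy locations; TI* pools TI and CA (one subject's ileum was unreachable)
BIOPSY_LOCATIONS = ("TI", "CA", "TC", "RE")
RANKS = ("phylum", "class", "genus", "species")


@dataclass
class MGS:
    mgs_id: str
    members: frozenset[str]
    centroids: tuple[str, ...]
    taxonomy: dict[str, str]  # rank -> label

    def __post_init__(self) -> None:
        if len(self.members) <= 100:
            raise ValueError(
                f"{self.mgs_id}: an MGS needs > 100 member genes, "
                f"got {len(self.members)}"
            )
        if not set(self.centroids) <= self.members:
            raise ValueError(f"{self.mgs_id}: centroids must be member genes")
        if not self.centroids:
            raise ValueError(f"{self.mgs_id}: no centroid genes listed")
        missing = [r for r in RANKS if r not in self.taxonomy]
        if missing:
            raise ValueError(f"{self.mgs_id}: taxonomy missing ranks {missing}")


class MGSSet:
    """Collection of MGS clusters; genes belong to at most one MGS."""

    def __init__(self, mgs_list: list[MGS]):
        ids = [m.mgs_id for m in mgs_list]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate MGS ids")
        seen: set[str] = set()
        for m in mgs_list:
            overlap = seen & m.members
            if overlap:
                raise ValueError(
                    f"gene(s) assigned to multiple MGSs, e.g. {sorted(overlap)[:3]}"
                )
            seen |= m.members
        self._mgs = {m.mgs_id: m for m in mgs_list}

    def __iter__(self):
        return iter(self._mgs.values())

    def __len__(self) -> int:
        return len(self._mgs)

    def __getitem__(self, mgs_id: str) -> MGS:
        return self._mgs[mgs_id]

    @property
    def ids(self) -> list[str]:
        return list(self._mgs)

    def taxonomy_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {m.mgs_id: m.taxonomy for m in self}, dtype=object
        ).T.loc[self.ids, list(RANKS)]


@dataclass
class SampleMetadata:
    """Sample -> (subject, location) map with group helpers."""

    table: pd.DataFrame  # index sample_id; columns subject_id, location

    def __post_init__(self) -> None:
        required = {"subject_id", "location"}
        if not required <= set(self.table.columns):
            raise ValueError(f"metadata needs columns {sorted(required)}")
        bad = set(self.table["location"]) - set(LOCATIONS)
        if bad:
            raise ValueError(f"unknown location code(s): {sorted(bad)}")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample ids")

    def samples(self, group: str) -> list[str]:
        """Samples in a location group.

        Besides the raw codes, accepts 'TI*' (TI pooled with CA), 'biopsy'
        (all non-faecal locations) and 'all'.
        """
        loc = self.table["location"]
        if group == "TI*":
            mask = loc.isin(["TI", "CA"])
        elif group == "biopsy":
            mask = loc.isin(BIOPSY_LOCATIONS)
        elif group == "all":
            mask = pd.Series(True, index=self.table.index)
        elif group in LOCATIONS:
            mask = loc == group
        else:
            raise KeyError(f"unknown sample group {group!r}")
        return list(self.table.index[mask])

    def subject_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "subject_id"])


def profile_mgs(gene_matrix: AbundanceMatrix, mgs_set: MGSSet) -> AbundanceMatrix:
    """MGS abundance = mean abundance of the cluster's centroid genes.

    Centroid genes absent from the matrix contribute abundance 0 but stay in
    the mean's denominator, keeping profiles comparable across samples.
    """
    rows = {}
    gene_index = gene_matrix.values.index
    for m in mgs_set:
        present = [g for g in m.centroids if g in gene_index]
        if present:
            total = gene_matrix.values.loc[present].sum(axis=0)
        else:
            total = pd.Series(0.0, index=gene_matrix.values.columns)
        rows[m.mgs_id] = total / len(m.centroids)
    df = pd.DataFrame(rows).T.loc[mgs_set.ids]
    return AbundanceMatrix(df, feature_axis="mgs", state=gene_matrix.state)


def mgs_richness(mgs_matrix: AbundanceMatrix,
                 detection_threshold: float = 0.0) -> pd.Series:
    """Number of MGSs with abundance > threshold per sample."""
    if detection_threshold < 0:
        raise ValueError("detection threshold must be >= 0")
    return (mgs_matrix.values > detection_threshold).sum(axis=0)


def _detected(mgs_matrix: AbundanceMatrix, samples: list[str]) -> set[str]:
    sub = mgs_matrix.values[samples]
    return set(sub.index[(sub > 0).any(axis=1)])


def shared_mgs_percentage(mgs_matrix: AbundanceMatrix, metadata: SampleMetadata,
                          group_a: str, group_b: str,
                          mode: str = "jaccard") -> float:
    """Percentage of MGSs shared between two location groups.

    An MGS counts as detected in a group if its abundance is > 0 in at least
    one of the group's samples. mode='jaccard' uses the union as denominator;
    mode='of_a' uses group A's detected set (one-sided sharing).
    """
    a = _detected(mgs_matrix, metadata.samples(group_a))
    b = _detected(mgs_matrix, metadata.samples(group_b))
    if not a | b:
        raise ValueError("no MGS detected in either group")
    if mode == "jaccard":
        return 100.0 * len(a & b) / len(a | b)
    if mode == "of_a":
        if not a:
            raise ValueError(f"no MGS detected in group {group_a!r}")
        return 100.0 * len(a & b) / len(a)
    raise ValueError(f"unknown mode {mode!r}")


def subject_sharing_percentage(mgs_matrix: AbundanceMatrix,
                               metadata: SampleMetadata,
                               sample_group: str = "biopsy") -> float:
    """Percent of detected MGSs found in at least two subjects of a group."""
    samples = metadata.samples(sample_group)
    subjects = {metadata.subject_of(s) for s in samples}
    if len(subjects) < 2:
        raise ValueError("need samples from >= 2 subjects")
    per_subject = {
        subj: _detected(mgs_matrix,
                        [s for s in samples if metadata.subject_of(s) == subj])
        for subj in subjects
    }
    detected_any = set().union(*per_subject.values())
    if not detected_any:
        raise ValueError("no MGS detected in the group")
    shared = [m for m in detected_any
              if sum(m in d for d in per_subject.values()) >= 2]
    return 100.0 * len(shared) / len(detected_any)


def aggregate_taxa(mgs_matrix: AbundanceMatrix, mgs_set: MGSSet,
                   rank: str) -> AbundanceMatrix:
    """Sum MGS abundances over a taxonomic rank (phylum/class/genus/species)."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose from {RANKS}")
    labels = pd.Series({m.mgs_id: m.taxonomy[rank] for m in mgs_set})
    labels = labels.reindex(mgs_matrix.features)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])[:5]
        raise KeyError(f"MGS(s) missing from the MGS set: {missing}")
    df = mgs_matrix.values.groupby(labels).sum()
    return AbundanceMatrix(df, feature_axis="taxon", state=mgs_matrix.state)


def top_taxa(taxon_matrix: AbundanceMatrix, metadata: SampleMetadata,
             k: int = 10, groups: tuple[str, ...] = ("TI*", "TC", "RE")) -> list[str]:
    """Top-k taxa ranked by mean abundance over the given biopsy groups."""
    samples: list[str] = []
    for g in groups:
        samples.extend(metadata.samples(g))
    means = taxon_matrix.values[samples].mean(axis=1)
    return list(means.sort_values(ascending=False).index[:k])
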