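"""End-to-end convenience pipeline used by the CLI and analysis scripts."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .mgs import MGSSet, SampleMetadata, aggregate_taxa, profile_mgs
from .quantify import (AbundanceMatrix, AlignmentSummary, counts_to_matrix,
                       length_normalize, rarefy, to_relative)
from .synth import SyntheticWorld


@dataclass
class PipelineResult:
    raw: AbundanceMatrix
    rarefied: AbundanceMatrix
    gene_abundance: AbundanceMatrix     # length-normalised
    mgs_profile: AbundanceMatrix
    genus_relative: AbundanceMatrix
    target_depth: int


def quantify_pipeline(summaries: dict[str, AlignmentSummary],
                      gene_lengths: pd.Series, mgs_set: MGSSet,
                      metadata: SampleMetadata, seed: int,
                      target_depth: int | None = None,
                      shared_policy: str = "equal") -> PipelineResult:
    """Alignment summaries -> rarefied, length-normalised gene and MGS tables.

    The default rarefaction depth is the minimum sample total of the jointly
    normalised set (biopsies and faeces downsized together).
    """
    raw = counts_to_matrix(list(summaries.values()),
                           gene_ids=list(gene_lengths.index),
                           policy=shared_policy)
    if target_depth is None:
        target_depth = int(raw.values.sum(axis=0).round().min())
    rarefied = rarefy(raw, target_depth, seed)
    gene_ab = length_normalize(rarefied, gene_lengths)
    mgs_prof = profile_mgs(gene_ab, mgs_set)
    genus = aggregate_taxa(mgs_prof, mgs_set, "genus")
    genus_rel = to_relative(genus) if genus.state != "relative" else genus
    return PipelineResult(raw=raw, rarefied=rarefied, gene_abundance=gene_ab,
                          mgs_profile=mgs_prof, genus_relative=genus_rel,
                          target_depth=target_depth)


def world_pipeline(world: SyntheticWorld, summaries: dict[str, AlignmentSummary],
                   seed: int, target_depth: int | None = None) -> PipelineResult:
    return quantify_pipeline(summaries, world.gene_lengths, world.mgs_set,
                             world.metadata, seed, target_depth)
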