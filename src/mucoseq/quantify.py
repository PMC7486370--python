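"""Gene abundance estimation from alignment summaries.

Implements the standard shotgun-metagenomics quantification chain: shared
(multi-mapped) read resolution, rarefaction ("downsizing") to a common read
depth, gene-length normalisation, and richness. Abundance tables move through
an explicit state machine ``raw_counts -> rarefied -> length_normalized ->
relative`` so that downstream consumers can assert what normalisation has
already happened.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AlignmentSummary",
    "AbundanceMatrix",
    "resolve_shared_counts",
    "counts_to_matrix",
    "rarefy",
    "length_normalize",
    "to_relative",
    "gene_richness",
]

_STATES = ("raw_counts", "rarefied", "length_normalized", "relative")


@dataclass
class AlignmentSummary:
    """Per-sample mapping summary against a gene catalogue.

    Parameters
    ----------
    sample_id : str
    unique_counts : dict
        gene_id -> uniquely mapped read count (non-negative int).
    shared_groups : list of (frozenset, int)
        Each entry is a group of >= 2 homologous target genes that a set of
        multi-mapped reads hit, with the read count of that group.
    covered_fraction : dict
        gene_id -> fraction of the gene's length covered by mapped reads.
    """

    sample_id: str
    unique_counts: dict[str, int]
    shared_groups: list[tuple[frozenset[str], int]] = field(default_factory=list)
    covered_fraction: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, c in self.unique_counts.items():
            if c < 0:
                raise ValueError(f"negative unique count for gene {g!r}")
        for genes, c in self.shared_groups:
            if len(genes) < 2:
                raise ValueError("shared group must contain >= 2 genes")
            if c < 0:
                raise ValueError("negative shared group count")
        for g, f in self.covered_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"covered fraction for {g!r} outside [0, 1]")

    @property
    def total_reads(self) -> int:
        return sum(self.unique_counts.values()) + sum(
            c for _, c in self.shared_groups
        )


class AbundanceMatrix:
    """Features x samples abundance table with tracked normalisation state.

    Wraps a pandas DataFrame (rows = genes, MGSs or taxa; columns = samples).
    State transitions are only allowed forward along
    raw_counts -> rarefied -> length_normalized -> relative.
    """

    def __init__(self, values: pd.DataFrame, feature_axis: str = "gene",
                 state: str = "raw_counts"):
        if state not in _STATES:
            raise ValueError(f"unknown state {state!r}")
        if feature_axis not in ("gene", "mgs", "taxon"):
            raise ValueError(f"unknown feature axis {feature_axis!r}")
        if (values.values < 0).any():
            raise ValueError("abundance values must be non-negative")
        if state == "relative":
            sums = values.sum(axis=0).to_numpy()
            if not np.allclose(sums[sums > 0], 1.0, atol=1e-9):
                raise ValueError("relative-state columns must sum to 1")
        self.values = values
        self.feature_axis = feature_axis
        self.state = state

    def _advance(self, new_values: pd.DataFrame, new_state: str,
                 feature_axis: str | None = None) -> "AbundanceMatrix":
        if _STATES.index(new_state) <= _STATES.index(self.state):
            raise ValueError(
                f"illegal state transition {self.state!r} -> {new_state!r}"
            )
        return AbundanceMatrix(new_values, feature_axis or self.feature_axis,
                               new_state)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    def __repr__(self) -> str:  # pragma: no cover
        r, c = self.values.shape
        return (f"AbundanceMatrix({r} {self.feature_axis}s x {c} samples, "
                f"state={self.state})")


def resolve_shared_counts(summary: AlignmentSummary, *,
                          policy: str = "equal",
                          known_genes: set[str] | None = None
                          ) -> dict[str, float]:
    """Combine unique and multi-mapped read counts into per-gene counts.

    Gene abundance is the sum of uniquely mapped reads plus each shared
    group's reads normalised over the group's target genes ("occurrences").

    policy='equal' splits a group's reads 1/k over its k genes;
    policy='weighted' splits proportionally to the genes' unique counts
    (falling back to an equal split when no member has unique reads).
    Total read mass is conserved under both policies. When ``known_genes``
    is given (the catalogue universe), shared groups referencing genes
    outside it are rejected; genes with zero unique reads are always legal.
    """
    if policy not in ("equal", "weighted"):
        raise ValueError(f"unknown shared-count policy {policy!r}")
    counts: dict[str, float] = {g: float(c) for g, c in summary.unique_counts.items()}
    for genes, group_count in summary.shared_groups:
        if known_genes is not None:
            unknown = sorted(set(genes) - known_genes)
            if unknown:
                raise KeyError(
                    "shared group references unknown gene(s): "
                    + ", ".join(unknown))
        members = sorted(genes)
        if policy == "weighted":
            weights = np.array([summary.unique_counts.get(g, 0) for g in members],
                               dtype=float)
            if weights.sum() == 0:
                weights[:] = 1.0
            weights /= weights.sum()
        else:
            weights = np.full(len(members), 1.0 / len(members))
        for g, w in zip(members, weights):
            counts[g] = counts.get(g, 0.0) + group_count * w
    return counts


def counts_to_matrix(summaries: list[AlignmentSummary], *,
                     gene_ids: list[str] | None = None,
                     policy: str = "equal") -> AbundanceMatrix:
    """Resolve each sample's summary and assemble a raw-count matrix."""
    known = set(gene_ids) if gene_ids is not None else None
    cols = {}
    for s in summaries:
        cols[s.sample_id] = resolve_shared_counts(s, policy=policy,
                                                  known_genes=known)
    df = pd.DataFrame(cols).fillna(0.0)
    if gene_ids is not None:
        df = df.reindex(gene_ids, fill_value=0.0)
    return AbundanceMatrix(df, feature_axis="gene", state="raw_counts")


def _largest_remainder_round(col: np.ndarray) -> np.ndarray:
    """Round a non-negative real vector to integers preserving its total.

    Floors every entry, then hands the leftover units to the entries with
    the largest fractional parts (ties broken by index for determinism).
    """
    floors = np.floor(col).astype(np.int64)
    remainder = int(round(col.sum())) - int(floors.sum())
    if remainder > 0:
        frac = col - floors
        order = np.lexsort((np.arange(len(col)), -frac))
        floors[order[:remainder]] += 1
    return floors


def rarefy(matrix: AbundanceMatrix, target_depth: int,
           seed: int | np.random.Generator) -> AbundanceMatrix:
    """Downsize every sample to ``target_depth`` reads without replacement.

    Each column is subsampled with a multivariate hypergeometric draw, the
    standard model of picking ``target_depth`` reads out of the sample's
    read pool. Real-valued columns (after shared-read resolution) are first
    rounded with a largest-remainder rule so totals are preserved.
    """
    if matrix.state != "raw_counts":
        raise ValueError("rarefy expects a raw_counts matrix")
    if target_depth <= 0:
        raise ValueError("target_depth must be positive")
    totals = matrix.values.sum(axis=0)
    shallow = [s for s, t in totals.items() if round(t) < target_depth]
    if shallow:
        raise ValueError(
            "sample(s) shallower than target depth "
            f"{target_depth}: {', '.join(map(str, shallow))}"
        )
    rng = np.random.default_rng(seed)
    out = {}
    for s in matrix.samples:
        col = _largest_remainder_round(matrix.values[s].to_numpy(dtype=float))
        out[s] = rng.multivariate_hypergeometric(col, target_depth,
                                                 method="marginals")
    df = pd.DataFrame(out, index=matrix.values.index, dtype=float)
    return matrix._advance(df, "rarefied")


def length_normalize(matrix: AbundanceMatrix,
                     lengths: dict[str, float] | pd.Series) -> AbundanceMatrix:
    """Divide counts by gene length in kilobases (reads per kb)."""
    lengths = pd.Series(lengths, dtype=float)
    missing = [g for g in matrix.features if g not in lengths.index]
    if missing:
        raise KeyError(f"missing gene length(s): {', '.join(missing[:5])}")
    lens = lengths.reindex(matrix.features)
    bad = lens[lens <= 0]
    if len(bad):
        raise ValueError(f"non-positive gene length(s): {', '.join(bad.index[:5])}")
    df = matrix.values.div(lens / 1000.0, axis=0)
    return matrix._advance(df, "length_normalized")


def to_relative(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Normalise each sample to relative abundances (columns sum to 1)."""
    sums = matrix.values.sum(axis=0)
    if (sums == 0).any():
        empty = list(sums[sums == 0].index)
        raise ValueError(f"all-zero sample(s): {', '.join(map(str, empty))}")
    return matrix._advance(matrix.values / sums, "relative")


def gene_richness(matrix: AbundanceMatrix, *,
                  threshold: float = 0.0) -> pd.Series:
    """Number of features detected (abundance > threshold) per sample."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return (matrix.values > threshold).sum(axis=0)
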