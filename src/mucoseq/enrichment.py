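"""KEGG-orthology pathway enrichment per gut location.

Genes detected at a location are mapped to their KEGG orthologs (KOs); each
pathway is then tested for over-representation of the location's detected
KOs against the catalogue background with a one-sided hypergeometric test.
Contributing species are ranked by the abundance their genes bring to the
pathway's KOs at that location.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .mgs import MGSSet, SampleMetadata
from .quantify import AbundanceMatrix

__all__ = [
    "KOAnnotation",
    "EnrichmentResult",
    "detected_kos",
    "pathway_enrichment",
    "contributing_species",
]


@dataclass
class KOAnnotation:
    gene_kos: dict[str, frozenset[str]]       # gene_id -> KO ids
    ko_pathways: dict[str, frozenset[str]]    # KO id -> pathway ids
    pathway_names: dict[str, str]             # pathway id -> name

    def __post_init__(self) -> None:
        referenced = set().union(*self.ko_pathways.values()) if self.ko_pathways else set()
        unnamed = referenced - set(self.pathway_names)
        if unnamed:
            raise ValueError(f"pathway id(s) missing a name: {sorted(unnamed)[:5]}")

    @property
    def all_kos(self) -> frozenset[str]:
        return frozenset().union(*self.gene_kos.values()) if self.gene_kos else frozenset()

    def pathway_kos(self, pathway_id: str) -> frozenset[str]:
        return frozenset(k for k, paths in self.ko_pathways.items()
                         if pathway_id in paths)


@dataclass
class EnrichmentResult:
    pathway_id: str
    pathway_name: str
    location: str
    overlap: int
    pathway_size: int
    n_detected: int
    n_background: int
    p: float
    q: float
    significant: bool  # raw p < 0.05, mirroring the uncorrected convention


def detected_kos(gene_matrix: AbundanceMatrix, annotation: KOAnnotation,
                 metadata: SampleMetadata, location: str) -> frozenset[str]:
    """Union of KO ids over genes detected (> 0) in the location's samples."""
    samples = metadata.samples(location)
    if not samples:
        raise ValueError(f"no samples for location {location!r}")
    sub = gene_matrix.values[samples]
    genes = sub.index[(sub > 0).any(axis=1)]
    kos: set[str] = set()
    for g in genes:
        kos |= annotation.gene_kos.get(g, frozenset())
    return frozenset(kos)


def pathway_enrichment(detected: frozenset[str], background: frozenset[str],
                       annotation: KOAnnotation, location: str = "",
                       alpha: float = 0.05) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation test per pathway.

    Drawing ``|detected|`` KOs from a ``|background|``-KO urn that contains
    the pathway's KOs as successes, p = P(X >= observed overlap). Raw p and
    a BH-adjusted q are both reported; the ``significant`` flag uses raw
    p < alpha.
    """
    if not detected <= background:
        stray = sorted(detected - background)[:5]
        raise ValueError(f"detected KOs outside the background: {stray}")
    N, n = len(background), len(detected)
    pathways = sorted(annotation.pathway_names)
    rows = []
    for pid in pathways:
        cat = annotation.pathway_kos(pid) & background
        K = len(cat)
        k = len(cat & detected)
        # survival function at k-1 gives P(X >= k)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((pid, K, k, min(p, 1.0)))
    qvals = multipletests([r[3] for r in rows], method="fdr_bh")[1]
    return [
        EnrichmentResult(
            pathway_id=pid, pathway_name=annotation.pathway_names[pid],
            location=location, overlap=k, pathway_size=K,
            n_detected=n, n_background=N, p=p, q=float(q),
            significant=p < alpha)
        for (pid, K, k, p), q in zip(rows, qvals)
    ]


def contributing_species(pathway_id: str, location: str,
                         gene_matrix: AbundanceMatrix, mgs_set: MGSSet,
                         annotation: KOAnnotation,
                         metadata: SampleMetadata) -> pd.DataFrame:
    """Rank MGSs by their abundance-weighted contribution to a pathway.

    An MGS's contribution is the summed location-mean abundance of its genes
    annotated to the pathway's KOs; fractions are normalised to sum to 1.
    """
    kos = annotation.pathway_kos(pathway_id)
    pathway_genes = {g for g, ks in annotation.gene_kos.items() if ks & kos}
    if not pathway_genes:
        import warnings
        warnings.warn(f"pathway {pathway_id!r} has no annotated genes",
                      stacklevel=2)
        return pd.DataFrame(columns=["mgs_id", "species", "contribution",
                                     "fraction"])
    means = gene_matrix.values[metadata.samples(location)].mean(axis=1)
    rows = []
    for m in mgs_set:
        genes = [g for g in (m.members & pathway_genes) if g in means.index]
        contrib = float(means[genes].sum()) if genes else 0.0
        if contrib > 0:
            rows.append({"mgs_id": m.mgs_id,
                         "species": m.taxonomy["species"],
                         "contribution": contrib})
    df = pd.DataFrame(rows, columns=["mgs_id", "species", "contribution"])
    if len(df):
        df = df.sort_values(["contribution", "mgs_id"],
                            ascending=[False, True]).reset_index(drop=True)
        df["fraction"] = df["contribution"] / df["contribution"].sum()
    else:
        df["fraction"] = pd.Series(dtype=float)
    return df
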