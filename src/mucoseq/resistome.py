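"""Antimicrobial-resistance-gene (ARG) profiling along the gut.

ARGs are catalogue genes annotated (CARD-style) with one or more drug
classes and resistance mechanisms. The analysis chain is: discard ARGs whose
read coverage in a sample is below 90% of the gene, count reads per ARG,
normalise samples with DESeq2's median-of-ratios size factors, then test
location-level enrichment of drug classes / mechanisms with the exact paired
Wilcoxon test plus Benjamini–Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .diversity import CorrelationReport, group_spearman, wilcoxon_signed_rank
from .mgs import SampleMetadata
from .quantify import AbundanceMatrix, AlignmentSummary, resolve_shared_counts

__all__ = [
    "ARGRecord",
    "MECHANISMS",
    "filter_by_coverage",
    "arg_count_matrix",
    "arg_richness",
    "size_factors",
    "normalize",
    "aggregate_by_annotation",
    "differential_enrichment",
    "resistome_correlation",
]

#: the CARD resistance-mechanism vocabulary used throughout
MECHANISMS = (
    "Antibiotic efflux",
    "Antibiotic inactivation",
    "Antibiotic target alteration",
    "Antibiotic target replacement",
    "Reduced permeability to antibiotic",
)


@dataclass
class ARGRecord:
    arg_id: str
    gene_id: str
    drug_classes: frozenset[str]
    mechanisms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.drug_classes:
            raise ValueError(f"{self.arg_id}: needs >= 1 drug class")
        if not self.mechanisms:
            raise ValueError(f"{self.arg_id}: needs >= 1 resistance mechanism")


def filter_by_coverage(records: list[ARGRecord],
                       summaries: list[AlignmentSummary],
                       min_cov: float = 0.90) -> pd.DataFrame:
    """Per-sample ARG detection after the coverage filter.

    An ARG survives in a sample iff its gene's covered fraction is
    >= ``min_cov`` (coverage *below* the threshold is discarded, so exactly
    90% survives) and it has at least one mapped read. Returns a boolean
    ARG x sample frame. Idempotent by construction.
    """
    out = {}
    by_gene = {r.gene_id: r for r in records}
    for s in summaries:
        counts = resolve_shared_counts(s)
        col = {}
        for gene_id, rec in by_gene.items():
            cov = s.covered_fraction.get(gene_id, 0.0)
            col[rec.arg_id] = bool(cov >= min_cov and counts.get(gene_id, 0.0) > 0)
        out[s.sample_id] = col
    return pd.DataFrame(out)


def arg_count_matrix(records: list[ARGRecord],
                     summaries: list[AlignmentSummary],
                     min_cov: float = 0.90) -> AbundanceMatrix:
    """Raw ARG read counts per sample, zeroed where the coverage filter fails."""
    detected = filter_by_coverage(records, summaries, min_cov)
    by_gene = {r.gene_id: r for r in records}
    cols = {}
    for s in summaries:
        counts = resolve_shared_counts(s)
        col = {}
        for gene_id, rec in by_gene.items():
            c = counts.get(gene_id, 0.0)
            col[rec.arg_id] = float(c) if detected.loc[rec.arg_id, s.sample_id] else 0.0
        cols[s.sample_id] = col
    df = pd.DataFrame(cols)
    return AbundanceMatrix(df, feature_axis="gene", state="raw_counts")


def arg_richness(detected: pd.DataFrame,
                 metadata: SampleMetadata | None = None,
                 groups: tuple[str, ...] = ("TI*", "TC", "RE", "FE")) -> pd.Series:
    """Distinct ARGs per sample, or per location group when metadata given."""
    per_sample = detected.sum(axis=0)
    if metadata is None:
        return per_sample
    return pd.Series({
        g: int(detected[metadata.samples(g)].any(axis=1).sum()) for g in groups
    })


def size_factors(matrix: AbundanceMatrix | pd.DataFrame,
                 reference: str = "strict") -> pd.Series:
    """DESeq2 median-of-ratios sample size factors.

    reference='strict': the per-ARG geometric mean over samples is computed
    over ARGs positive in every sample; factor(s) = median over those ARGs
    of count(a, s) / geomean(a). reference='poscounts': sparse-data variant
    — per-ARG geometric means use positive entries only and each sample's
    median runs over the ARGs it actually carries.
    """
    df = matrix.values if isinstance(matrix, AbundanceMatrix) else matrix
    X = df.to_numpy(dtype=float)
    if reference == "strict":
        ref_rows = (X > 0).all(axis=1)
        if not ref_rows.any():
            raise ValueError(
                "no ARG has positive counts in every sample; median-of-ratios "
                "needs an all-positive reference set (use the 'poscounts' "
                "pseudo-reference over the positive subset)")
        logs = np.log(X[ref_rows])
        log_geomean = logs.mean(axis=1, keepdims=True)
        # median taken in ratio space (matters for even reference counts)
        factors = np.median(np.exp(logs - log_geomean), axis=0)
    elif reference == "poscounts":
        logs = np.full_like(X, np.nan)
        np.log(X, where=X > 0, out=logs)
        log_geomean = np.nanmean(logs, axis=1, keepdims=True)
        factors = np.nanmedian(np.exp(logs - log_geomean), axis=0)
        if np.isnan(factors).any():
            bad = list(df.columns[np.isnan(factors)])
            raise ValueError(f"sample(s) with no detected ARG: {bad}")
    else:
        raise ValueError(f"unknown reference scheme {reference!r}")
    return pd.Series(factors, index=df.columns, name="size_factor")


def normalize(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Counts divided by their sample's median-of-ratios size factor.

    Falls back to the 'poscounts' pseudo-reference when no ARG is shared by
    all samples (the usual situation after per-sample coverage filtering).
    """
    try:
        sf = size_factors(matrix, reference="strict")
    except ValueError:
        sf = size_factors(matrix, reference="poscounts")
    return matrix.values / sf


def aggregate_by_annotation(normalized: pd.DataFrame, records: list[ARGRecord],
                            grouping: str, *,
                            unique_class: bool = False) -> pd.DataFrame:
    """Sum normalised ARG abundance per drug class or mechanism.

    ARGs carrying several labels contribute to each (CARD convention), which
    double-counts mass across labels; ``unique_class=True`` restricts to
    single-label ARGs for conservation-sensitive analyses.
    """
    if grouping == "arg":
        return normalized.copy()
    if grouping not in ("drug_class", "mechanism"):
        raise ValueError(f"unknown grouping {grouping!r}")
    attr = "drug_classes" if grouping == "drug_class" else "mechanisms"
    rows: dict[str, pd.Series] = {}
    for rec in records:
        labels = getattr(rec, attr)
        if unique_class and len(labels) > 1:
            continue
        if rec.arg_id not in normalized.index:
            continue
        for lab in labels:
            if lab in rows:
                rows[lab] = rows[lab] + normalized.loc[rec.arg_id]
            else:
                rows[lab] = normalized.loc[rec.arg_id].copy()
    return pd.DataFrame(rows).T.sort_index()


def differential_enrichment(matrix: AbundanceMatrix, metadata: SampleMetadata,
                            records: list[ARGRecord],
                            grouping: str = "mechanism",
                            groups: tuple[str, ...] = ("TI*", "TC", "RE", "FE"),
                            ) -> pd.DataFrame:
    """Location enrichment of ARG features (class/mechanism/gene level).

    For every feature and location, a paired exact Wilcoxon test compares,
    within each subject, the feature's normalised abundance at that location
    against the subject's mean over the remaining locations. BH correction
    runs over features within each location contrast. The output reports
    per-location means, so enrichment direction can be read off directly.
    """
    norm = aggregate_by_annotation(normalize(matrix), records, grouping)
    norm = norm.loc[norm.sum(axis=1) > 0]  # all-zero features dropped
    loc_samples = {g: metadata.samples(g) for g in groups}
    subjects = sorted(set(metadata.table["subject_id"]))
    results = []
    for g in groups:
        others = [x for x in groups if x != g]
        pvals, feats, stats, mean_in, mean_out = [], [], [], [], []
        for feat in norm.index:
            xs, ys = [], []
            for subj in subjects:
                own = [s for s in loc_samples[g]
                       if metadata.subject_of(s) == subj]
                rest = [s for o in others for s in loc_samples[o]
                        if metadata.subject_of(s) == subj]
                if own and rest:
                    xs.append(norm.loc[feat, own].mean())
                    ys.append(norm.loc[feat, rest].mean())
            xs, ys = np.asarray(xs), np.asarray(ys)
            try:
                w, p = wilcoxon_signed_rank(xs, ys)
            except ValueError:  # all differences zero -> uninformative
                w, p = np.nan, 1.0
            feats.append(feat)
            stats.append(w)
            pvals.append(p)
            mean_in.append(float(xs.mean()) if len(xs) else np.nan)
            mean_out.append(float(ys.mean()) if len(ys) else np.nan)
        q = multipletests(pvals, method="fdr_bh")[1]
        for i, feat in enumerate(feats):
            results.append({
                "feature": feat, "level": grouping, "location": g,
                "mean_in": mean_in[i], "mean_out": mean_out[i],
                "direction": "up" if mean_in[i] > mean_out[i] else "down",
                "W": stats[i], "p": pvals[i], "q": float(q[i]),
            })
    return pd.DataFrame(results)


def resistome_correlation(matrix: AbundanceMatrix, metadata: SampleMetadata,
                          pairs: list[tuple[str, str]] | None = None
                          ) -> list[CorrelationReport]:
    """Spearman correlations between location resistomes (normalised ARGs)."""
    norm = AbundanceMatrix(normalize(matrix), feature_axis="gene",
                           state=matrix.state)
    if pairs is None:
        pairs = [("biopsy", "TI*"), ("biopsy", "TC"), ("biopsy", "RE"),
                 ("biopsy", "FE")]
    return [group_spearman(norm, metadata, a, b) for a, b in pairs]
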