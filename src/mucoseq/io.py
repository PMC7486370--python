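"""Plain-text readers and writers for the pipeline's tabular formats.

All tables are TSV; the reaction database and diet are JSON. Schemas:

catalogue.tsv    gene_id, length_bp, mgs_id, phylum, class, genus, species,
                 ko_ids (';'-joined), arg_id, drug_classes, mechanisms
<sample>.aln.tsv record_type (unique|shared), gene_id or ';'-joined gene
                 list, read_count, covered_fraction (unique records only)
metadata.tsv     sample_id, subject_id, location
matrix.tsv       features x samples with a header row of sample ids
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .enrichment import KOAnnotation
from .gem import DietConstraint, UniversalReactionDB
from .mgs import MGS, MGSSet, SampleMetadata
from .quantify import AbundanceMatrix, AlignmentSummary
from .resistome import ARGRecord

__all__ = [
    "write_catalogue", "read_catalogue", "mgs_set_from_catalogue",
    "arg_records_from_catalogue", "ko_annotation_from_catalogue",
    "write_alignment_summary", "read_alignment_summary",
    "write_metadata", "read_metadata",
    "write_matrix", "read_matrix",
    "write_world",
]


def write_catalogue(catalogue: pd.DataFrame, path: str | Path) -> None:
    catalogue.to_csv(path, sep="\t", index=False)


def read_catalogue(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "mgs_id": str},
                     keep_default_na=False)
    df["length_bp"] = df["length_bp"].astype(int)
    return df


def mgs_set_from_catalogue(catalogue: pd.DataFrame,
                           n_centroids: int = 50) -> MGSSet:
    """Rebuild the MGS clustering from catalogue rows.

    The first ``n_centroids`` genes of each cluster (catalogue order) are
    its centroid genes.
    """
    mgs_list = []
    for mgs_id, sub in catalogue.groupby("mgs_id", sort=True):
        genes = list(sub["gene_id"])
        row = sub.iloc[0]
        mgs_list.append(MGS(
            mgs_id=str(mgs_id), members=frozenset(genes),
            centroids=tuple(genes[:n_centroids]),
            taxonomy={r: str(row[r]) for r in
                      ("phylum", "class", "genus", "species")},
        ))
    return MGSSet(mgs_list)


def arg_records_from_catalogue(catalogue: pd.DataFrame) -> list[ARGRecord]:
    out = []
    for _, row in catalogue[catalogue["arg_id"] != ""].iterrows():
        out.append(ARGRecord(
            arg_id=row["arg_id"], gene_id=row["gene_id"],
            drug_classes=frozenset(row["drug_classes"].split(";")),
            mechanisms=frozenset(row["mechanisms"].split(";")),
        ))
    return out


def ko_annotation_from_catalogue(catalogue: pd.DataFrame,
                                 ko_pathways: dict[str, frozenset[str]],
                                 pathway_names: dict[str, str]) -> KOAnnotation:
    gene_kos = {
        row["gene_id"]: frozenset(row["ko_ids"].split(";"))
        for _, row in catalogue.iterrows() if row["ko_ids"]
    }
    return KOAnnotation(gene_kos=gene_kos, ko_pathways=ko_pathways,
                        pathway_names=pathway_names)


def write_alignment_summary(summary: AlignmentSummary, path: str | Path) -> None:
    rows = []
    for g, c in sorted(summary.unique_counts.items()):
        rows.append({"record_type": "unique", "gene_ids": g, "read_count": c,
                     "covered_fraction": summary.covered_fraction.get(g, "")})
    for genes, c in summary.shared_groups:
        rows.append({"record_type": "shared", "gene_ids": ";".join(sorted(genes)),
                     "read_count": c, "covered_fraction": ""})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_alignment_summary(path: str | Path,
                           sample_id: str | None = None) -> AlignmentSummary:
    path = Path(path)
    sample_id = sample_id or path.name.split(".")[0]
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    unique, shared, covered = {}, [], {}
    for _, row in df.iterrows():
        if row["record_type"] == "unique":
            unique[row["gene_ids"]] = int(row["read_count"])
            if row["covered_fraction"] != "":
                covered[row["gene_ids"]] = float(row["covered_fraction"])
        else:
            shared.append((frozenset(row["gene_ids"].split(";")),
                           int(row["read_count"])))
    return AlignmentSummary(sample_id, unique, shared, covered)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.table.rename_axis("sample_id").to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return SampleMetadata(df.rename_axis(None))


def write_matrix(matrix: AbundanceMatrix, path: str | Path) -> None:
    matrix.values.rename_axis(matrix.feature_axis).to_csv(path, sep="\t")


def read_matrix(path: str | Path, state: str = "raw_counts") -> AbundanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    axis = df.index.name if df.index.name in ("gene", "mgs", "taxon") else "gene"
    return AbundanceMatrix(df.rename_axis(None), feature_axis=axis,
                           state=state)


def write_world(world, outdir: str | Path,
                summaries: dict[str, AlignmentSummary] | None = None) -> None:
    """Write every pipeline input a synthetic world provides."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_catalogue(world.catalogue, outdir / "catalogue.tsv")
    write_metadata(world.metadata, outdir / "metadata.tsv")
    world.true_profiles.rename_axis("mgs").to_csv(
        outdir / "true_profiles.tsv", sep="\t")
    (outdir / "reaction_universe.json").write_text(
        world.reaction_universe.to_json())
    (outdir / "diet.json").write_text(world.diet.to_json())
    pd.DataFrame(
        [{"ko_id": k, "pathway_id": pid,
          "pathway_name": world.annotation.pathway_names[pid]}
         for k, pids in world.annotation.ko_pathways.items()
         for pid in sorted(pids)]
    ).to_csv(outdir / "ko_pathways.tsv", sep="\t", index=False)
    if summaries:
        aln = outdir / "alignments"
        aln.mkdir(exist_ok=True)
        for s, summ in summaries.items():
            write_alignment_summary(summ, aln / f"{s}.aln.tsv")
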