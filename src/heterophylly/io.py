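"""Readers and writers for the pipeline's on-disk formats.

Tables are tab-delimited with a header row; sequences are FASTA (T or U
accepted, normalized to the RNA alphabet downstream); annotation maps come
as two-column ``term_id<TAB>gene_id`` files or GMT; ground truth and run
manifests are JSON.  Site coordinates in pair tables are 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import CountMatrix, TranscriptStructure
from .simulate import SyntheticDataset, TruthTable
from .targeting import TargetPair

logger = logging.getLogger(__name__)


# -- tab-delimited tables ----------------------------------------------------

def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    matrix.counts.rename_axis("rna_id").to_csv(path, sep="\t")


def read_counts(
    path: str | Path, sample_sheet: pd.DataFrame, rna_class: str = "mRNA"
) -> CountMatrix:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    groups = sample_sheet.set_index("sample_id")["group"]
    missing = set(counts.columns) - set(groups.index)
    if missing:
        raise ValueError(
            f"{path}: samples missing from the sample sheet: {sorted(missing)}"
        )
    return CountMatrix(counts=counts, groups=groups, rna_class=rna_class)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return sheet


def read_leaf_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"sample_id", "length_cm", "width_cm"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: leaf table missing columns {sorted(missing)}")
    return table


# -- FASTA -------------------------------------------------------------------

def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    if any("T" in s or "t" in s for s in seqs.values()):
        logger.info("%s: DNA alphabet detected; T will be read as U", path)
    return seqs


# -- GTF/GFF3 transcript structures ------------------------------------------

def read_transcript_structures(path: str | Path) -> list[TranscriptStructure]:
    """Transcript length (summed exon length) and exon count from GTF/GFF3."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_transcripts=True, disable_infer_genes=True,
    )
    structures = []
    for tx in db.features_of_type(("transcript", "mRNA")):
        exons = list(db.children(tx, featuretype="exon"))
        if exons:
            length = sum(e.end - e.start + 1 for e in exons)
            n = len(exons)
        else:
            length, n = tx.end - tx.start + 1, 1
        structures.append(TranscriptStructure(tx.id, length, n))
    return structures


# -- annotation maps ---------------------------------------------------------

def read_annotation_map(path: str | Path, universe: Iterable[str] | None = None):
    """Two-column (term, gene) TSV or GMT, by extension (.gmt)."""
    from .enrichment import AnnotationMap

    path = Path(path)
    terms: dict[str, set] = {}
    if path.suffix.lower() == ".gmt":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            terms[fields[0]] = set(fields[2:])  # field 1 is the description
    else:
        df = pd.read_csv(path, sep="\t", header=None, names=["term_id", "gene_id"])
        for term, sub in df.groupby("term_id"):
            terms[str(term)] = set(sub["gene_id"].astype(str))
    if universe is None:
        universe = set().union(*terms.values()) if terms else set()
    return AnnotationMap(terms=terms, universe=set(universe))


def write_annotation_map(annotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(annotation.terms):
            for gene in sorted(annotation.terms[term]):
                fh.write(f"{term}\t{gene}\n")


# -- pairs, truth, manifest --------------------------------------------------

def write_target_pairs(pairs: Iterable[TargetPair], path: str | Path) -> None:
    rows = [dataclasses.asdict(p) for p in pairs]
    pd.DataFrame(
        rows,
        columns=["small_rna_id", "transcript_id", "expectation", "site_start", "site_seq"],
    ).to_csv(path, sep="\t", index=False)


def read_target_pairs(path: str | Path) -> list[TargetPair]:
    df = pd.read_csv(path, sep="\t").fillna({"site_seq": ""})
    return [TargetPair(**row) for row in df.to_dict("records")]


def write_truth(truth: TruthTable, path: str | Path) -> None:
    Path(path).write_text(truth.to_json())


def read_truth(path: str | Path) -> TruthTable:
    return TruthTable.from_json(Path(path).read_text())


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic dataset to disk in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for cls, matrix in dataset.counts.items():
        paths[f"counts_{cls}"] = outdir / f"counts_{cls}.tsv"
        write_counts(matrix, paths[f"counts_{cls}"])
    paths["sample_sheet"] = outdir / "samples.tsv"
    write_sample_sheet(dataset.sample_sheet, paths["sample_sheet"])
    paths["leaf_table"] = outdir / "leaves.tsv"
    dataset.leaf_table.to_csv(paths["leaf_table"], sep="\t", index=False)
    paths["small_rnas"] = outdir / "small_rnas.fasta"
    write_fasta(dataset.small_rna_seqs, paths["small_rnas"])
    paths["transcripts"] = outdir / "transcripts.fasta"
    write_fasta(dataset.transcript_seqs, paths["transcripts"])
    paths["annotations"] = outdir / "annotations.tsv"
    write_annotation_map(dataset.annotations, paths["annotations"])
    paths["truth"] = outdir / "truth.json"
    write_truth(dataset.truth, paths["truth"])
    return paths
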