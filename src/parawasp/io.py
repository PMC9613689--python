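"""File-format adapters for the CLI and pipelines.

Coordinate conventions: BED intervals are 0-based half-open; GFF3-derived
gene models are converted to 0-based half-open on input.  FASTA goes
through Bio.SeqIO, alignments through Bio.AlignIO (MAF), trees through
dendropy.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from Bio import AlignIO, SeqIO

from .ltr import LtrDating, LtrPair
from .pirna import ReadHit, SmallRnaRead, TeInterval

__all__ = [
    "read_ltr_pairs_fasta",
    "write_dating_tsv",
    "read_reads_fasta",
    "read_hits_tsv",
    "read_te_bed",
    "read_maf",
    "read_expression_tsv",
    "read_sample_labels_tsv",
    "read_peptides_tsv",
    "read_gene_models_gff3",
    "write_gene_models_gff3",
]


def read_ltr_pairs_fasta(path: str) -> list[LtrPair]:
    """Read paired LTRs from FASTA; records are linked by a shared element id
    with ``_5p`` / ``_3p`` suffixes and must be pre-aligned (equal length).

    The first word of the description after the id, when present, is taken
    as the family label.
    """
    five: dict[str, SeqIO.SeqRecord] = {}
    three: dict[str, SeqIO.SeqRecord] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id.endswith("_5p"):
            five[rec.id[:-3]] = rec
        elif rec.id.endswith("_3p"):
            three[rec.id[:-3]] = rec
        else:
            raise ValueError(f"record {rec.id!r} lacks a _5p/_3p suffix")
    missing = set(five) ^ set(three)
    if missing:
        raise ValueError(f"unpaired element ids: {sorted(missing)[:5]}")
    pairs = []
    for eid in sorted(five):
        parts = five[eid].description.split()
        family = parts[1] if len(parts) > 1 else "unknown"
        pairs.append(
            LtrPair(
                element_id=eid,
                ltr5=str(five[eid].seq),
                ltr3=str(three[eid].seq),
                family=family,
            )
        )
    return pairs


def write_dating_tsv(datings: Iterable[LtrDating], path: str) -> None:
    rows = [
        {
            "element_id": d.element_id,
            "family": d.family,
            "P": d.P,
            "Q": d.Q,
            "K": d.K,
            "T": d.T,
            "r": d.r,
            "flag": d.flag,
        }
        for d in datings
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_reads_fasta(path: str) -> list[SmallRnaRead]:
    return [
        SmallRnaRead(read_id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(path, "fasta")
    ]


def read_hits_tsv(path: str) -> list[ReadHit]:
    """Read mapping records: read_id, target, start, strand, length,
    target_kind (tab-separated, with header)."""
    df = pd.read_csv(path, sep="\t")
    required = {"read_id", "target", "start", "strand", "length", "target_kind"}
    if not required <= set(df.columns):
        raise ValueError(f"hits table must have columns {sorted(required)}")
    return [
        ReadHit(
            read_id=row.read_id,
            target_id=row.target,
            start=int(row.start),
            strand=row.strand,
            length=int(row.length),
            target_kind=row.target_kind,
        )
        for row in df.itertuples()
    ]


def read_te_bed(path: str) -> list[TeInterval]:
    """BED with columns chrom, start, end, class, family (0-based half-open)."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"BED line needs >= 4 columns: {line!r}")
            intervals.append(
                TeInterval(
                    target_id=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    te_class=fields[3],
                    family=fields[4] if len(fields) > 4 else "",
                )
            )
    return intervals


def read_maf(path: str):
    return list(AlignIO.parse(path, "maf"))


def read_expression_tsv(path: str) -> pd.DataFrame:
    """Genes x samples TPM table; first column = gene_id."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_sample_labels_tsv(path: str) -> dict[str, str]:
    """Two-column table: sample, label."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_peptides_tsv(path: str) -> dict[str, int]:
    """Two-column table: gene_id, n_peptides."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(int)))


GeneModel = tuple[str, str, int, int, str, list[tuple[int, int]]]


def read_gene_models_gff3(path: str) -> list[GeneModel]:
    """Gene models (gene + exon features) from GFF3, converted from the
    1-based inclusive GFF convention to 0-based half-open tuples
    (gene_id, chrom, start, end, strand, exons)."""
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons = sorted(
            (e.start - 1, e.end) for e in db.children(gene, featuretype="exon")
        )
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        models.append(
            (gene.id, gene.seqid, gene.start - 1, gene.end, gene.strand, exons)
        )
    return models


def write_gene_models_gff3(models: Iterable[GeneModel], path: str) -> None:
    """Write gene models as GFF3 (1-based inclusive on output)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, chrom, start, end, strand, exons in models:
            fh.write(
                f"{chrom}\tparawasp\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\t"
                f"ID={gene_id}\n"
            )
            for i, (s, e) in enumerate(exons, 1):
                fh.write(
                    f"{chrom}\tparawasp\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                    f"ID={gene_id}.exon{i};Parent={gene_id}\n"
                )
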