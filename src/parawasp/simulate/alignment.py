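"""Pairwise whole-genome alignment blocks with planted low-conservation
segments inside regulatory regions.

The reference genome is tiled by fully identical two-species alignment
blocks except at planted intervals, which are left unaligned (no block
covers them) — the footprint a recent TE insertion leaves in a pairwise
alignment.  Ground truth records each planted interval so NRER detection
can be scored exactly.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ..regulatory import RegulatoryRegion, regions_from_gene_models

__all__ = ["gen_alignment_blocks"]

_BASES = "ACGT"
REF_SPECIES = "refsp"
OTHER_SPECIES = "qrysp"


def _block(chrom: str, start: int, seq: str, src_size: int) -> MultipleSeqAlignment:
    ref = SeqRecord(Seq(seq), id=f"{REF_SPECIES}.{chrom}")
    ref.annotations = {
        "start": start,
        "size": len(seq),
        "strand": 1,
        "srcSize": src_size,
    }
    qry = SeqRecord(Seq(seq), id=f"{OTHER_SPECIES}.{chrom}")
    qry.annotations = {
        "start": start,
        "size": len(seq),
        "strand": 1,
        "srcSize": src_size,
    }
    return MultipleSeqAlignment([ref, qry])


def gen_alignment_blocks(
    gene_models: list[tuple[str, str, int, int, str, list[tuple[int, int]]]],
    nrer_spec: list[tuple[str, str, int]],
    te_insertions: list[tuple[str, int, int]] | None = None,
    chrom_sizes: dict[str, int] | None = None,
    seed: int = 0,
    block_size: int = 500,
) -> tuple[list[MultipleSeqAlignment], list[RegulatoryRegion], dict]:
    """Emit MAF-style alignment blocks with planted unaligned segments.

    Parameters
    ----------
    gene_models : (gene_id, chrom, start, end, strand, exons) tuples with
        0-based half-open coordinates.
    nrer_spec : planted divergent segments as (gene_id, region_class,
        length); each is centred inside a matching regulatory region of
        that gene.  A segment that fits in no such region raises.
    te_insertions : optional (chrom, start, end) intervals; ground truth
        notes which planted segments they overlap by >= half their length.
    block_size : aligned blocks are split at most this long (and at planted
        boundaries), exercising invariance to block splitting.

    Returns (blocks, regions, ground_truth); ``regions`` are the
    regulatory regions of the input gene models (detector input), and
    ground truth lists each planted interval.
    """
    rng = np.random.default_rng(seed)
    regions = regions_from_gene_models(gene_models, chrom_sizes=chrom_sizes)
    by_gene_class: dict[tuple[str, str], list[RegulatoryRegion]] = {}
    for r in regions:
        by_gene_class.setdefault((r.gene_id, r.region_class), []).append(r)

    planted: list[dict] = []
    for gene_id, region_class, length in nrer_spec:
        candidates = [
            r
            for r in by_gene_class.get((gene_id, region_class), [])
            if r.end - r.start >= length
        ]
        if not candidates:
            raise ValueError(
                f"no {region_class} region of {gene_id} can hold a "
                f"{length} bp planted segment"
            )
        region = candidates[0]
        slack = (region.end - region.start) - length
        offset = slack // 2
        start = region.start + offset
        planted.append(
            {
                "gene_id": gene_id,
                "region_class": region_class,
                "chrom": region.chrom,
                "start": start,
                "end": start + length,
                "length": length,
            }
        )

    if chrom_sizes is None:
        chrom_sizes = {}
        for _, chrom, start, end, _, _ in gene_models:
            chrom_sizes[chrom] = max(chrom_sizes.get(chrom, 0), end + 2000)

    if te_insertions:
        for entry in planted:
            overlap = sum(
                max(0, min(e, entry["end"]) - max(s, entry["start"]))
                for chrom, s, e in te_insertions
                if chrom == entry["chrom"]
            )
            entry["te_overlap_bp"] = overlap
            entry["te_overlapped"] = overlap >= entry["length"] / 2
    else:
        for entry in planted:
            entry["te_overlap_bp"] = 0
            entry["te_overlapped"] = False

    blocks: list[MultipleSeqAlignment] = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        holes = sorted(
            (p["start"], p["end"]) for p in planted if p["chrom"] == chrom
        )
        aligned_segments = []
        cursor = 0
        for s, e in holes:
            if s > cursor:
                aligned_segments.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < size:
            aligned_segments.append((cursor, size))
        for seg_start, seg_end in aligned_segments:
            pos = seg_start
            while pos < seg_end:
                end = min(pos + block_size, seg_end)
                seq = "".join(
                    _BASES[b] for b in rng.integers(0, 4, size=end - pos)
                )
                blocks.append(_block(chrom, pos, seq, size))
                pos = end

    truth = {"planted": planted, "ref_species": REF_SPECIES}
    return blocks, regions, truth
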