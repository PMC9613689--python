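"""Regulatory divergence between closely related genomes.

Covers four linked analyses: (i) Spearman correlation of ortholog
expression profiles across matched developmental stages; (ii) a rank-sum
test of whether recent TE insertions near a gene depress that correlation;
(iii) detection of non-coding rapidly evolving regions (NRERs) — runs of
poorly aligned sequence longer than 60 bp inside a gene's potential
regulatory regions (1 kb upstream/downstream and introns) — from pairwise
whole-genome alignment; and (iv) a chi-square test of NRER enrichment in
genes whose venom-gland expression shifted strongly between species
(fold change > 6) versus stable genes (fold change < 1.25).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .stats import Chi2Result, RankSumResult, chi2_2x2, spearman, wilcoxon_ranksum

__all__ = [
    "RegulatoryRegion",
    "Nrer",
    "ortholog_expression_correlation",
    "te_insertion_effect_test",
    "detect_nrers",
    "attribute_te",
    "classify_expression_shift",
    "shift_enrichment",
    "regions_from_gene_models",
]

NRER_MIN_LEN = 60  # NRERs must be strictly longer than this (bp)
NRER_MAX_IDENTITY = 0.5
NRER_WINDOW = 20
NRER_MERGE_GAP = 10
FOLDCHANGE_PSEUDOCOUNT = 0.1
LARGE_SHIFT_FC = 6.0
STABLE_FC = 1.25
REGULATORY_FLANK = 1000
TE_ATTRIBUTION_FRACTION = 0.5


@dataclass(frozen=True)
class RegulatoryRegion:
    """A potential regulatory interval of a gene (0-based half-open)."""

    gene_id: str
    region_class: str  # upstream_1kb | downstream_1kb | intron
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty region [{self.start}, {self.end})")


@dataclass
class Nrer:
    """A non-coding rapidly evolving region within a regulatory region."""

    gene_id: str
    region_class: str
    chrom: str
    start: int
    end: int
    te_attributed: bool = False
    flag: str = "ok"  # or "no_coverage"

    @property
    def length(self) -> int:
        return self.end - self.start


def ortholog_expression_correlation(
    pairs: Mapping[str, tuple[Sequence[float], Sequence[float]]],
) -> dict[str, float]:
    """Spearman rho per ortholog pair over matched stage vectors.

    ``pairs`` maps a pair id to the two expression vectors (same stage
    order).  Pairs with fewer than 4 stages raise; a constant vector yields
    ``nan`` (correlation undefined).
    """
    out: dict[str, float] = {}
    for pid, (a, b) in pairs.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size != b.size:
            raise ValueError(f"{pid}: vectors differ in length")
        if a.size < 4:
            raise ValueError(f"{pid}: need >= 4 matched samples, got {a.size}")
        out[pid] = spearman(a, b)[0]
    return out


def te_insertion_effect_test(
    rho_insertion: Sequence[float], rho_no_insertion: Sequence[float]
) -> RankSumResult:
    """Two-sided rank-sum test comparing ortholog expression correlations of
    genes with vs without a recent nearby TE insertion."""
    return wilcoxon_ranksum(rho_insertion, rho_no_insertion)


def regions_from_gene_models(
    genes: Iterable[tuple[str, str, int, int, str, list[tuple[int, int]]]],
    flank: int = REGULATORY_FLANK,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[RegulatoryRegion]:
    """Regulatory regions (1 kb upstream/downstream + introns) of gene models.

    ``genes`` yields (gene_id, chrom, start, end, strand, exons) with
    0-based half-open gene/exon coordinates; exons sorted by start.
    Upstream/downstream respect strand and are clipped at chromosome ends.
    """
    regions: list[RegulatoryRegion] = []
    for gene_id, chrom, start, end, strand, exons in genes:
        size = chrom_sizes.get(chrom) if chrom_sizes else None
        left = (max(0, start - flank), start)
        right = (end, end + flank if size is None else min(size, end + flank))
        up, down = (left, right) if strand != "-" else (right, left)
        if up[1] > up[0]:
            regions.append(
                RegulatoryRegion(gene_id, "upstream_1kb", chrom, up[0], up[1], strand)
            )
        if down[1] > down[0]:
            regions.append(
                RegulatoryRegion(gene_id, "downstream_1kb", chrom, down[0], down[1], strand)
            )
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 > e1:
                regions.append(
                    RegulatoryRegion(gene_id, "intron", chrom, e1, s2, strand)
                )
    return regions


def _reference_identity_tracks(
    maf_blocks, ref_species: str
) -> dict[str, dict[int, bool]]:
    """Per-chromosome map: reference position -> column identical to partner.

    Positions aligned to a gap (or N) in the partner, and positions covered
    by no block, are simply absent/False and count as non-identical.
    """
    tracks: dict[str, dict[int, bool]] = {}
    for block in maf_blocks:
        ref_row = None
        other_rows = []
        for rec in block:
            src = rec.id
            if src.split(".", 1)[0] == ref_species:
                ref_row = rec
            else:
                other_rows.append(rec)
        if ref_row is None or not other_rows:
            continue
        ann = ref_row.annotations
        if ann.get("strand", 1) not in (1, "+"):
            raise ValueError("reference MAF rows must be on the + strand")
        chrom = ref_row.id.split(".", 1)[1] if "." in ref_row.id else ref_row.id
        track = tracks.setdefault(chrom, {})
        pos = int(ann["start"])
        ref_seq = str(ref_row.seq).upper()
        other_seqs = [str(r.seq).upper() for r in other_rows]
        for col, ref_char in enumerate(ref_seq):
            if ref_char == "-":
                continue
            identical = any(
                s[col] == ref_char and s[col] in "ACGT" for s in other_seqs
            )
            # a position hit by several blocks stays identical if any block says so
            track[pos] = identical or track.get(pos, False)
            pos += 1
    return tracks


def detect_nrers(
    maf_blocks,
    regions: Sequence[RegulatoryRegion],
    ref_species: str,
    min_len: int = NRER_MIN_LEN,
    max_identity: float = NRER_MAX_IDENTITY,
    window: int = NRER_WINDOW,
    merge_gap: int = NRER_MERGE_GAP,
) -> list[Nrer]:
    """Detect NRERs inside regulatory regions from a pairwise alignment.

    Within each region every reference base is scored identical (aligned and
    matching) or divergent (mismatch, aligned-to-gap, or unaligned).  Bases
    whose ``window``-wide neighbourhood has identity <= ``max_identity``
    seed candidate runs; runs are trimmed to their outermost divergent
    bases, merged when separated by fewer than ``merge_gap`` identical
    bases, and reported when strictly longer than ``min_len``.

    A region with no alignment coverage at all is returned whole as a
    single candidate flagged ``no_coverage``.
    """
    blocks = list(maf_blocks)
    tracks = _reference_identity_tracks(blocks, ref_species)
    out: list[Nrer] = []
    half = window // 2
    for region in regions:
        track = tracks.get(region.chrom, {})
        L = region.end - region.start
        covered = np.zeros(L, dtype=bool)
        identical = np.zeros(L, dtype=bool)
        for i in range(L):
            pos = region.start + i
            if pos in track:
                covered[i] = True
                identical[i] = track[pos]
        if not covered.any():
            out.append(
                Nrer(
                    region.gene_id,
                    region.region_class,
                    region.chrom,
                    region.start,
                    region.end,
                    flag="no_coverage",
                )
            )
            continue
        divergent = ~identical  # unaligned counts as divergent
        # windowed identity around each base, clipped at the region edges
        csum = np.concatenate([[0], np.cumsum(identical)])
        lo = np.maximum(np.arange(L) - half, 0)
        hi = np.minimum(np.arange(L) + window - half, L)
        win_identity = (csum[hi] - csum[lo]) / (hi - lo)
        candidate = win_identity <= max_identity

        runs = _runs(candidate)
        trimmed = []
        for s, e in runs:
            idx = np.nonzero(divergent[s:e])[0]
            if idx.size == 0:
                continue
            trimmed.append((s + int(idx[0]), s + int(idx[-1]) + 1))
        merged: list[list[int]] = []
        for s, e in trimmed:
            if merged and s - merged[-1][1] < merge_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            if e - s > min_len:
                out.append(
                    Nrer(
                        region.gene_id,
                        region.region_class,
                        region.chrom,
                        region.start + s,
                        region.start + e,
                    )
                )
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean array as half-open (start, end) pairs."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def attribute_te(
    nrers: Sequence[Nrer],
    recent_te_intervals: Sequence[tuple[str, int, int]],
    min_fraction: float = TE_ATTRIBUTION_FRACTION,
) -> float:
    """Flag NRERs explained by recent TE insertions; return the attributed
    fraction.

    An NRER is TE-attributed when at least ``min_fraction`` of its length
    overlaps recent TE intervals ((chrom, start, end), 0-based half-open).
    Flags are set in place on the ``Nrer`` objects.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in recent_te_intervals:
        if e <= s:
            raise ValueError(f"malformed TE interval [{s}, {e}) on {chrom}")
        by_chrom.setdefault(chrom, []).append((s, e))

    n_attr = 0
    for nrer in nrers:
        overlap = 0
        for s, e in by_chrom.get(nrer.chrom, ()):
            overlap += max(0, min(e, nrer.end) - max(s, nrer.start))
        nrer.te_attributed = overlap >= min_fraction * nrer.length
        n_attr += nrer.te_attributed
    return n_attr / len(nrers) if nrers else 0.0


def classify_expression_shift(
    tpm_vg_a: float,
    tpm_vg_b: float,
    pseudocount: float = FOLDCHANGE_PSEUDOCOUNT,
    large_fc: float = LARGE_SHIFT_FC,
    stable_fc: float = STABLE_FC,
) -> str:
    """Classify the between-species venom-gland fold change of an ortholog
    pair: ``large_shift`` (FC > 6), ``stable`` (FC < 1.25) or
    ``intermediate``.  A pseudocount keeps near-zero TPMs finite."""
    if tpm_vg_a < 0 or tpm_vg_b < 0:
        raise ValueError("TPM values must be non-negative")
    hi, lo = max(tpm_vg_a, tpm_vg_b), min(tpm_vg_a, tpm_vg_b)
    fc = (hi + pseudocount) / (lo + pseudocount)
    if fc > large_fc:
        return "large_shift"
    if fc < stable_fc:
        return "stable"
    return "intermediate"


def shift_enrichment(
    large_shift_genes: Sequence[str],
    stable_genes: Sequence[str],
    genes_with_nrer: set[str],
) -> Chi2Result:
    """Chi-square test of NRER enrichment in shifted vs stable genes.

    Counts genes (not individual NRERs) carrying at least one NRER in their
    regulatory regions, builds the 2x2 table
    [with-NRER, without-NRER] x [large_shift, stable], and applies
    Pearson's chi-square (1 df, no continuity correction).
    """
    if not large_shift_genes or not stable_genes:
        raise ValueError("both expression-shift classes must be nonempty")
    ls_with = sum(g in genes_with_nrer for g in large_shift_genes)
    st_with = sum(g in genes_with_nrer for g in stable_genes)
    table = [
        [ls_with, len(large_shift_genes) - ls_with],
        [st_with, len(stable_genes) - st_with],
    ]
    return chi2_2x2(table)
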