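"""piRNA profiling: length spectra, nucleotide biases, TE assignment and
Ping-Pong scoring.

piRNAs produced by the Ping-Pong amplification loop come in sense/antisense
pairs whose 5' ends overlap by exactly 10 nt, and carry a uridine bias at
position 1 (1U) and an adenine bias at position 10 (10A).  The strength of
the loop on a given transposon scope is summarised by the Z-score of the
10-nt bin of the 5'-to-5' overlap spectrum against the other bins.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .stats import spearman

__all__ = [
    "SmallRnaRead",
    "ReadHit",
    "TeInterval",
    "OverlapSpectrum",
    "PingPongScore",
    "filter_pirna_candidates",
    "length_distribution",
    "nt_bias",
    "assign_to_tes",
    "overlap_spectrum",
    "pingpong_z",
    "pingpong_by_family",
]

PIRNA_MIN_LEN = 24
PIRNA_MAX_LEN = 35
MAX_OVERLAP = 30


@dataclass(frozen=True)
class SmallRnaRead:
    """A trimmed small-RNA read; T and U are treated as equivalent."""

    read_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadHit:
    """One reported mapping of a read onto a genome scaffold or TE consensus.

    ``start`` is 0-based on the plus strand of the target; the read occupies
    ``[start, start + length)`` regardless of strand, so the 5' end of a
    minus-strand read sits at ``start + length - 1``.
    """

    read_id: str
    target_id: str
    start: int
    strand: str  # '+' or '-'
    length: int
    target_kind: str = "genome"  # 'genome' or 'te_consensus'

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.start + self.length - 1


@dataclass(frozen=True)
class TeInterval:
    """A TE annotation interval, 0-based half-open, with class/family labels."""

    target_id: str
    start: int
    end: int
    te_class: str
    family: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"malformed interval [{self.start}, {self.end}) on {self.target_id}"
            )


@dataclass
class OverlapSpectrum:
    """Counts of 5'-to-5' overlaps between opposite-strand read pairs."""

    counts: dict[int, float]
    scope: str = ""

    def as_array(self, max_overlap: int = MAX_OVERLAP) -> np.ndarray:
        return np.array(
            [self.counts.get(o, 0.0) for o in range(max_overlap + 1)], dtype=float
        )


@dataclass
class PingPongScore:
    scope: str
    z: float | None  # None when the background sd is zero
    n10: float
    background_mean: float
    background_sd: float


def filter_pirna_candidates(
    reads: Iterable[SmallRnaRead],
    ncrna_hits: set[str] = frozenset(),
    min_len: int = PIRNA_MIN_LEN,
    max_len: int = PIRNA_MAX_LEN,
) -> list[SmallRnaRead]:
    """Retain piRNA-length reads (24-35 nt) not flagged as structural ncRNA."""
    return [
        r
        for r in reads
        if r.read_id not in ncrna_hits and min_len <= r.length <= max_len
    ]


def length_distribution(
    reads: Iterable[SmallRnaRead],
    classes: Mapping[str, str] | None = None,
    min_len: int = 18,
    max_len: int = 35,
) -> dict[str, dict[int, int]]:
    """Read-length histogram per annotation class ('all' when no classes given).

    ``classes`` maps read_id to a class label (e.g. miRNA / siRNA / piRNA /
    other); unlisted reads fall into 'other'.
    """
    out: dict[str, dict[int, int]] = {}
    for r in reads:
        cls = "all" if classes is None else classes.get(r.read_id, "other")
        hist = out.setdefault(cls, {L: 0 for L in range(min_len, max_len + 1)})
        hist[r.length] = hist.get(r.length, 0) + 1
    return out


def nt_bias(reads: Sequence[SmallRnaRead], position: int) -> dict[str, float]:
    """Nucleotide frequencies at a 1-based position over reads reaching it.

    T is reported as U.  Reads shorter than ``position`` are excluded from
    the denominator; if none reaches it, a ``ValueError`` is raised.
    """
    if position < 1:
        raise ValueError("position is 1-based and must be >= 1")
    counts: Counter[str] = Counter()
    total = 0
    for r in reads:
        if r.length < position:
            continue
        nt = r.sequence[position - 1].upper().replace("T", "U")
        counts[nt] += 1
        total += 1
    if total == 0:
        raise ValueError(f"no read reaches position {position}")
    return {nt: c / total for nt, c in sorted(counts.items())}


def assign_to_tes(
    genome_hits: Sequence[ReadHit], te_annotation: Sequence[TeInterval]
) -> dict[str, object]:
    """Assign genome-mapped reads to TE classes by interval overlap.

    A read counts toward a TE class when its mapped interval overlaps a TE
    interval by >= 1 bp; among multiple overlapping classes the one with the
    longest total overlap wins (ties break lexicographically).  Reads
    overlapping no TE count as ``non-TE``.
    """
    by_target: dict[str, list[TeInterval]] = defaultdict(list)
    for iv in te_annotation:
        by_target[iv.target_id].append(iv)
    for ivs in by_target.values():
        ivs.sort(key=lambda iv: iv.start)

    class_counts: Counter[str] = Counter()
    for hit in genome_hits:
        r_start, r_end = hit.start, hit.start + hit.length
        overlap_by_class: Counter[str] = Counter()
        for iv in by_target.get(hit.target_id, ()):
            if iv.start >= r_end:
                break
            ov = min(r_end, iv.end) - max(r_start, iv.start)
            if ov > 0:
                overlap_by_class[iv.te_class] += ov
        if overlap_by_class:
            best = min(
                overlap_by_class.items(), key=lambda kv: (-kv[1], kv[0])
            )[0]
            class_counts[best] += 1
        else:
            class_counts["non-TE"] += 1

    total = sum(class_counts.values())
    fractions = {c: n / total for c, n in class_counts.items()} if total else {}
    te_total = total - class_counts.get("non-TE", 0)
    return {
        "counts": dict(class_counts),
        "fractions": fractions,
        "te_fraction": te_total / total if total else 0.0,
        "n_reads": total,
    }


def overlap_spectrum(
    te_hits: Iterable[ReadHit],
    scope: str = "",
    max_overlap: int = MAX_OVERLAP,
    collapse_positions: bool = False,
) -> OverlapSpectrum:
    """5'-to-5' overlap spectrum of opposite-strand hits on TE consensus space.

    For a plus-strand 5' end at ``p`` and a minus-strand 5' end at ``q``
    (plus-strand coordinates), the overlap is ``o = q - p + 1``, so a
    canonical Ping-Pong pair scores exactly 10.  Each (p, q) position pair
    with ``0 <= o <= max_overlap`` contributes ``min(count_p, count_q)``
    (read multiplicities at the two 5' positions), or 1 when
    ``collapse_positions`` is set.
    """
    plus: dict[tuple[str, int], int] = defaultdict(int)
    minus: dict[tuple[str, int], int] = defaultdict(int)
    for hit in te_hits:
        key = (hit.target_id, hit.five_prime)
        (plus if hit.strand == "+" else minus)[key] += 1

    counts = {o: 0.0 for o in range(max_overlap + 1)}
    for (target, p), cp in plus.items():
        for o in range(max_overlap + 1):
            cq = minus.get((target, p + o - 1))
            if cq:
                counts[o] += 1 if collapse_positions else min(cp, cq)
    return OverlapSpectrum(counts=counts, scope=scope)


def pingpong_z(spectrum: OverlapSpectrum) -> PingPongScore:
    """Ping-Pong score: Z of the 10-nt bin against all other overlap bins.

    The background is every bin except o=10; its dispersion uses the sample
    (n-1) standard deviation.  A zero-variance background yields ``z=None``.
    """
    n10 = spectrum.counts.get(10, 0.0)
    background = np.array(
        [c for o, c in spectrum.counts.items() if o != 10], dtype=float
    )
    if background.size < 2:
        raise ValueError("spectrum needs at least two background bins")
    mu = float(background.mean())
    sd = float(background.std(ddof=1))
    z = None if sd == 0 else (n10 - mu) / sd
    return PingPongScore(
        scope=spectrum.scope, z=z, n10=n10, background_mean=mu, background_sd=sd
    )


def pingpong_by_family(
    te_hits: Sequence[ReadHit],
    family_map: Mapping[str, str],
    family_ages: Mapping[str, float] | None = None,
) -> dict[str, object]:
    """Per-family Ping-Pong scores and their rank correlation with family age.

    ``family_map`` maps consensus target_id to family; ``family_ages`` gives
    the family median insertion age (My), typically from the LTR dating
    stage.  The age-score Spearman correlation is skipped (with a note in
    the report) when fewer than three families have both quantities.
    """
    by_family: dict[str, list[ReadHit]] = defaultdict(list)
    for hit in te_hits:
        fam = family_map.get(hit.target_id)
        if fam is not None:
            by_family[fam].append(hit)

    scores: dict[str, PingPongScore] = {}
    for fam, hits in sorted(by_family.items()):
        scores[fam] = pingpong_z(overlap_spectrum(hits, scope=fam))

    report: dict[str, object] = {"scores": scores, "rho": None, "pvalue": None}
    if family_ages is not None:
        fams = [
            f
            for f in scores
            if scores[f].z is not None and f in family_ages
        ]
        if len(fams) < 3:
            report["note"] = "fewer than 3 families with defined Z and age"
        else:
            ages = [family_ages[f] for f in fams]
            zs = [scores[f].z for f in fams]
            rho, p = spearman(ages, zs)
            report["rho"], report["pvalue"] = rho, p
    return report
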