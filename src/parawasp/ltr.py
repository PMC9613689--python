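"""Dating LTR retrotransposon insertions from paired-LTR divergence.

The two long terminal repeats of a retrotransposon are identical at the
moment of insertion; substitutions accumulate independently in each copy
afterwards.  The Kimura two-parameter (K2P) distance ``K`` between the 5'
and 3' LTRs therefore measures twice the time since insertion scaled by the
lineage substitution rate ``r``::

    T = K / (2 r)

with ``T`` in million years (My) when ``r`` is in substitutions/site/My.
Solo LTRs, the relics of unequal homologous recombination, are summarised
by the solo:intact ratio as an index of TE elimination.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "LtrPair",
    "LtrDating",
    "SaturationError",
    "DEFAULT_RATE",
    "kimura2p",
    "insertion_time",
    "date_pairs",
    "age_histogram",
    "solo_intact_ratio",
    "align_ltr_pair",
]

#: Fallback lineage substitution rate (subs/site/My).  This is a generic
#: insect nuclear rate used only when the caller supplies none; lineage
#: rates differ several-fold, so users must supply their own estimate
#: (e.g. from a dated phylogeny) for absolute ages to be meaningful.
DEFAULT_RATE = 0.0029

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


class SaturationError(ValueError):
    """Raised when the K2P log arguments are non-positive (distance undefined)."""


@dataclass
class LtrPair:
    """Aligned 5'/3' LTR sequences of one full-length retrotransposon."""

    element_id: str
    ltr5: str
    ltr3: str
    family: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.ltr5) != len(self.ltr3):
            raise ValueError(
                f"{self.element_id}: aligned LTR lengths differ "
                f"({len(self.ltr5)} vs {len(self.ltr3)})"
            )


@dataclass
class LtrDating:
    """K2P dating result for one element; ``flag`` marks saturated/failed pairs."""

    element_id: str
    family: str = "unknown"
    P: float = float("nan")
    Q: float = float("nan")
    K: float = float("nan")
    T: float = float("nan")
    r: float = float("nan")
    flag: str = "ok"


def kimura2p(ltr5: str, ltr3: str) -> tuple[float, float, float]:
    """Kimura two-parameter distance between two aligned sequences.

    Columns with a gap or ``N`` in either sequence are excluded (pairwise
    deletion).  Over the remaining comparable columns, ``P`` is the
    transition proportion, ``Q`` the transversion proportion, and

        K = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

    Raises
    ------
    ValueError
        If the aligned lengths differ or no comparable column remains.
    SaturationError
        If ``1 - 2P - Q <= 0`` or ``1 - 2Q <= 0`` (distance undefined).
    """
    if len(ltr5) != len(ltr3):
        raise ValueError("aligned sequences must have equal length")
    a = ltr5.upper()
    b = ltr3.upper()
    sites = transitions = transversions = 0
    for x, y in zip(a, b):
        if x not in _VALID or y not in _VALID:
            continue
        sites += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        raise ValueError("no comparable (ungapped, non-N) columns")
    P = transitions / sites
    Q = transversions / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P undefined for P={P:.4f}, Q={Q:.4f} (saturated divergence)"
        )
    K = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return P, Q, K


def insertion_time(K: float, r: float) -> float:
    """Insertion time T = K / (2 r) in My; ``r`` in subs/site/My."""
    if r <= 0:
        raise ValueError(f"substitution rate must be positive, got {r}")
    if K < 0:
        raise ValueError(f"K must be non-negative, got {K}")
    return K / (2.0 * r)


def date_pairs(pairs: Iterable[LtrPair], rate: float | None = None) -> list[LtrDating]:
    """Date a collection of LTR pairs; saturated pairs are flagged, not dropped."""
    if rate is None:
        warnings.warn(
            "no lineage substitution rate supplied; using the generic default "
            f"r={DEFAULT_RATE} subs/site/My — absolute ages will be unreliable",
            stacklevel=2,
        )
        rate = DEFAULT_RATE
    if rate <= 0:
        raise ValueError(f"substitution rate must be positive, got {rate}")
    out: list[LtrDating] = []
    for pair in pairs:
        d = LtrDating(element_id=pair.element_id, family=pair.family, r=rate)
        try:
            d.P, d.Q, d.K = kimura2p(pair.ltr5, pair.ltr3)
            d.T = insertion_time(d.K, rate)
        except SaturationError:
            d.flag = "saturated"
        except ValueError:
            d.flag = "no_sites"
        out.append(d)
    return out


@dataclass
class AgeHistogram:
    """Per-family binned insertion-time counts plus excluded (flagged) tallies."""

    bin_width: float
    bins: dict[str, dict[int, int]] = field(default_factory=dict)
    excluded: dict[str, int] = field(default_factory=dict)

    def counts(self, family: str) -> dict[int, int]:
        return self.bins.get(family, {})


def age_histogram(datings: Iterable[LtrDating], bin_width: float) -> AgeHistogram:
    """Bin insertion times per family; bin ``i`` covers [i*w, (i+1)*w)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    hist = AgeHistogram(bin_width=bin_width)
    for d in datings:
        if d.flag != "ok":
            hist.excluded[d.flag] = hist.excluded.get(d.flag, 0) + 1
            continue
        idx = int(d.T // bin_width)
        fam = hist.bins.setdefault(d.family, {})
        fam[idx] = fam.get(idx, 0) + 1
    return hist


#: Sentinel returned when the intact count is zero and the ratio is undefined.
UNDEFINED_RATIO = None


def solo_intact_ratio(n_solo: int, n_intact: int) -> float | None:
    """Solo-LTR : intact-element ratio; ``None`` when no intact element exists."""
    if n_solo < 0 or n_intact < 0:
        raise ValueError("counts must be non-negative")
    if n_intact == 0:
        return UNDEFINED_RATIO
    return n_solo / n_intact


def align_ltr_pair(seq5: str, seq3: str) -> tuple[str, str]:
    """Globally align two unaligned LTR copies (match 1, mismatch -1, gap -2).

    Convenience only: production pipelines should align with a dedicated
    aligner and feed pre-aligned pairs to :func:`kimura2p`.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aln = aligner.align(seq5.upper(), seq3.upper())[0]
    return str(aln[0]), str(aln[1])
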