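"""Small-RNA read populations with planted Ping-Pong pairs and 1U/10A biases.

A planted fraction of reads comes in sense/antisense pairs on a TE
consensus whose 5' ends overlap by exactly 10 nt (the Ping-Pong
signature); the remainder are placed uniformly on random strands.  First-
position U and 10th-position A biases are applied to every read so that
measured biases match the configured proportions.
"""

from __future__ import annotations

import numpy as np

from ..pirna import ReadHit, SmallRnaRead

__all__ = ["make_te_consensus", "gen_small_rna"]

_BASES = "ACGT"
PINGPONG_OVERLAP = 10


def make_te_consensus(
    n_families: int = 4, length: int = 3000, seed: int = 0
) -> dict[str, str]:
    """Random TE consensus sequences named ``TE00``, ``TE01``, ..."""
    rng = np.random.default_rng(seed)
    return {
        f"TE{i:02d}": "".join(
            _BASES[b] for b in rng.integers(0, 4, size=length)
        )
        for i in range(n_families)
    }


def _random_read(
    rng: np.random.Generator, length: int, u1_bias: float, a10_bias: float
) -> str:
    seq = [_BASES[b] for b in rng.integers(0, 4, size=length)]
    # exact biases: the biased nucleotide with the stated probability,
    # otherwise one of the other three uniformly
    seq[0] = "T" if rng.random() < u1_bias else "ACG"[rng.integers(3)]
    if length >= 10:
        seq[9] = "A" if rng.random() < a10_bias else "CGT"[rng.integers(3)]
    return "".join(seq)


def gen_small_rna(
    n_reads: int,
    pingpong_fraction: float,
    u1_bias: float = 0.8,
    a10_bias: float = 0.6,
    te_consensus: dict[str, str] | None = None,
    len_range: tuple[int, int] = (24, 30),
    seed: int = 0,
) -> tuple[list[SmallRnaRead], list[ReadHit], dict]:
    """Simulate TE-consensus-mapped small RNA reads.

    ``pingpong_fraction`` of the reads form plus/minus pairs whose 5' ends
    overlap by exactly 10 nt; the rest are placed uniformly.  Returns
    (reads, hits, ground_truth); ground truth lists the planted pair read
    ids and the realised planted fraction.
    """
    if not 0.0 <= pingpong_fraction <= 1.0:
        raise ValueError("pingpong_fraction must be in [0, 1]")
    if not (18 <= len_range[0] <= len_range[1] <= 35):
        raise ValueError("len_range must lie within [18, 35]")
    if te_consensus is None:
        te_consensus = make_te_consensus(seed=seed)
    if not te_consensus:
        raise ValueError("te_consensus must contain at least one sequence")

    rng = np.random.default_rng(seed)
    targets = sorted(te_consensus)
    reads: list[SmallRnaRead] = []
    hits: list[ReadHit] = []
    planted_ids: list[str] = []
    n_pairs = int(round(pingpong_fraction * n_reads / 2))
    counter = 0

    def new_id() -> str:
        nonlocal counter
        rid = f"read{counter:07d}"
        counter += 1
        return rid

    lo, hi = len_range
    for _ in range(n_pairs):
        target = targets[rng.integers(len(targets))]
        tlen = len(te_consensus[target])
        l_plus = int(rng.integers(lo, hi + 1))
        l_minus = int(rng.integers(lo, hi + 1))
        # plus 5' at p, minus 5' at q = p + 9 so the overlap o = q - p + 1 = 10
        p = int(rng.integers(l_minus, tlen - l_plus))
        q = p + PINGPONG_OVERLAP - 1
        rid_p, rid_m = new_id(), new_id()
        reads.append(SmallRnaRead(rid_p, _random_read(rng, l_plus, u1_bias, a10_bias)))
        reads.append(SmallRnaRead(rid_m, _random_read(rng, l_minus, u1_bias, a10_bias)))
        hits.append(ReadHit(rid_p, target, p, "+", l_plus, "te_consensus"))
        hits.append(
            ReadHit(rid_m, target, q - l_minus + 1, "-", l_minus, "te_consensus")
        )
        planted_ids.extend([rid_p, rid_m])

    for _ in range(n_reads - 2 * n_pairs):
        target = targets[rng.integers(len(targets))]
        tlen = len(te_consensus[target])
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, tlen - length))
        strand = "+" if rng.random() < 0.5 else "-"
        rid = new_id()
        reads.append(SmallRnaRead(rid, _random_read(rng, length, u1_bias, a10_bias)))
        hits.append(ReadHit(rid, target, start, strand, length, "te_consensus"))

    truth = {
        "planted_pair_reads": planted_ids,
        "planted_fraction": 2 * n_pairs / n_reads if n_reads else 0.0,
        "u1_bias": u1_bias,
        "a10_bias": a10_bias,
    }
    return reads, hits, truth
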