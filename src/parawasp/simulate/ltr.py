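"""Paired-LTR sequences diverged under a two-rate substitution process.

Each element starts from one ancestral LTR sequence; the two copies then
evolve independently along branches of ``rate * age_my`` expected
substitutions per site under a Kimura two-rate (transition/transversion)
process, so the summed expected divergence between the copies is
``2 * rate * age_my`` and the K2P estimator downstream is exactly matched
to the generating model.
"""

from __future__ import annotations

import math

import numpy as np

from ..ltr import LtrPair

__all__ = ["gen_ltr_pairs", "ltr_pairs_to_fasta"]

_BASES = np.array(list("ACGT"))
# transition partner of A, C, G, T (indices into _BASES)
_TRANSITION = np.array([2, 3, 0, 1])
# the two transversion partners of each base
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


def _k80_branch_probs(d: float, kappa: float) -> tuple[float, float]:
    """(transition prob, per-target transversion prob) after a branch of
    ``d`` expected substitutions/site with ts/tv ratio ``kappa``."""
    beta_t = d / (kappa + 2.0)
    alpha_t = kappa * beta_t
    e1 = math.exp(-4.0 * beta_t)
    e2 = math.exp(-2.0 * (alpha_t + beta_t))
    p_transition = 0.25 + 0.25 * e1 - 0.5 * e2
    p_transversion_each = 0.25 - 0.25 * e1
    return p_transition, p_transversion_each


def _evolve(seq_idx: np.ndarray, d: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    p_ts, p_tv = _k80_branch_probs(d, kappa)
    u = rng.random(seq_idx.size)
    out = seq_idx.copy()
    ts_mask = u < p_ts
    out[ts_mask] = _TRANSITION[seq_idx[ts_mask]]
    tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[tv1] = _TRANSVERSIONS[seq_idx[tv1], 0]
    out[tv2] = _TRANSVERSIONS[seq_idx[tv2], 1]
    return out


def gen_ltr_pairs(
    n: int,
    age_my: float,
    rate: float,
    kappa: float = 2.0,
    ltr_len: int = 400,
    seed: int = 0,
    family: str = "Gypsy",
) -> tuple[list[LtrPair], dict]:
    """Simulate ``n`` paired LTRs of known insertion age.

    Parameters
    ----------
    age_my : true insertion age (My); each copy accrues ``rate * age_my``
        expected substitutions/site.
    rate : lineage substitution rate (subs/site/My), > 0.
    kappa : transition/transversion rate ratio of the substitution process.
    ltr_len : LTR length in bp (>= 50).

    Returns (pairs, ground_truth) where ground_truth records the true age,
    rate and kappa per element.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if ltr_len < 50:
        raise ValueError("ltr_len must be >= 50")
    if age_my < 0:
        raise ValueError("age_my must be non-negative")
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    d = rate * age_my
    pairs: list[LtrPair] = []
    truth_rows = {}
    for i in range(n):
        element_id = f"ltr{i:06d}"
        anc = rng.integers(0, 4, size=ltr_len)
        ltr5 = _evolve(anc, d, kappa, rng)
        ltr3 = _evolve(anc, d, kappa, rng)
        pairs.append(
            LtrPair(
                element_id=element_id,
                ltr5="".join(_BASES[ltr5]),
                ltr3="".join(_BASES[ltr3]),
                family=family,
            )
        )
        truth_rows[element_id] = {"age_my": age_my, "rate": rate, "kappa": kappa}
    return pairs, {"elements": truth_rows, "age_my": age_my, "rate": rate}


def ltr_pairs_to_fasta(pairs: list[LtrPair]) -> str:
    """FASTA text with paired ``_5p`` / ``_3p`` identifiers per element."""
    chunks = []
    for p in pairs:
        chunks.append(f">{p.element_id}_5p {p.family}\n{p.ltr5}\n")
        chunks.append(f">{p.element_id}_3p {p.family}\n{p.ltr3}\n")
    return "".join(chunks)
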