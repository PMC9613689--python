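"""Venom-gene calling from venom-gland expression plus proteomic support.

A gene is called a venom gene when (i) its venom-gland TPM exceeds the N90
expression threshold of the venom-gland sample — the TPM of the first gene,
in descending order, at which cumulative expression reaches 90% of the
sample total — and (ii) at least three fully matched proteomic peptides
from the venom-reservoir proteome support it.  Venom-gland specificity
(VG TPM over the best non-VG TPM) is reported descriptively and never
gates a call.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "VG_LABEL",
    "MIN_PEPTIDES",
    "average_replicates",
    "n90_threshold",
    "vg_specificity",
    "call_venom_genes",
]

VG_LABEL = "venom_gland"
MIN_PEPTIDES = 3
SPECIFICITY_PSEUDOCOUNT = 0.01


def average_replicates(
    matrix: pd.DataFrame, sample_labels: pd.Series | dict
) -> pd.DataFrame:
    """Average replicate columns sharing a label into one column per label."""
    labels = pd.Series(sample_labels)
    missing = [c for c in matrix.columns if c not in labels.index]
    if missing:
        raise ValueError(f"samples without a label: {missing[:5]}")
    return matrix.T.groupby(labels.loc[matrix.columns]).mean().T


def n90_threshold(vg_tpm: pd.Series | np.ndarray) -> float:
    """N90 of an expression vector: sort TPM descending; return the TPM of the
    first gene at which the cumulative sum reaches >= 90% of the total."""
    v = np.sort(np.asarray(vg_tpm, dtype=float))[::-1]
    if v.size == 0 or v[0] <= 0:
        raise ValueError("N90 undefined: no gene with positive TPM")
    if np.any(v < 0):
        raise ValueError("TPM values must be non-negative")
    cum = np.cumsum(v)
    idx = int(np.searchsorted(cum, 0.9 * cum[-1]))
    return float(v[idx])


def vg_specificity(vg_tpm: float, other_tpms: np.ndarray | list) -> float:
    """Descriptive venom-gland specificity: VG TPM over the maximum non-VG TPM
    plus a 0.01 pseudocount.  Not used in calling."""
    others = np.asarray(other_tpms, dtype=float)
    peak = float(others.max()) if others.size else 0.0
    return float(vg_tpm) / (peak + SPECIFICITY_PSEUDOCOUNT)


def call_venom_genes(
    matrix: pd.DataFrame,
    sample_labels: pd.Series | dict,
    peptide_support: pd.Series | dict,
    vg_label: str = VG_LABEL,
    min_peptides: int = MIN_PEPTIDES,
) -> pd.DataFrame:
    """Call venom genes: VG TPM strictly above N90 AND >= ``min_peptides``
    fully matched peptides.

    Parameters
    ----------
    matrix : genes x samples TPM table.
    sample_labels : sample -> stage/tissue label; one label must equal
        ``vg_label``.  Replicates sharing a label are averaged first.
    peptide_support : gene_id -> number of fully matched peptides; genes
        absent from the matrix are ignored with a warning.

    Returns a per-gene table (vg_tpm, n90_threshold, specificity,
    n_peptides, is_venom).
    """
    averaged = average_replicates(matrix, sample_labels)
    if vg_label not in averaged.columns:
        raise ValueError(f"no sample labelled {vg_label!r}")
    peptides = pd.Series(peptide_support, dtype=float)
    unknown = peptides.index.difference(matrix.index)
    if len(unknown):
        warnings.warn(
            f"{len(unknown)} gene(s) in the peptide table are absent from the "
            f"expression matrix and were ignored (e.g. {unknown[0]!r})",
            stacklevel=2,
        )
        peptides = peptides.drop(unknown)

    vg = averaged[vg_label]
    n90 = n90_threshold(vg)
    others = averaged.drop(columns=[vg_label])
    peak_other = others.max(axis=1) if others.shape[1] else pd.Series(0.0, index=vg.index)

    out = pd.DataFrame(index=averaged.index)
    out.index.name = "gene_id"
    out["vg_tpm"] = vg
    out["n90_threshold"] = n90
    out["specificity"] = vg / (peak_other + SPECIFICITY_PSEUDOCOUNT)
    out["n_peptides"] = peptides.reindex(out.index).fillna(0).astype(int)
    out["is_venom"] = (vg > n90) & (out["n_peptides"] >= min_peptides)
    return out
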