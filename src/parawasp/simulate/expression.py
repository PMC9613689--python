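"""Two-species developmental expression matrices with a planted venom module.

Both species share latent stage programs (factors).  Each gene's mean
profile is a mixture ``lambda * factor + (1 - lambda) * private`` of its
factor profile and a gene-specific private profile shared by the ortholog
pair, so the mixing weight ``lambda`` is the gene's true module
connectivity: high-lambda genes are module hubs, low-lambda genes its
periphery.  A planted gene block loads on a venom-gland-exclusive factor
in both species (the venom module); a planted subset of its venom-flagged
members loses venom-gland expression in species B (venom turnover by
expression shift); and a planted subset of its non-venom members — chosen
from the lowest-lambda periphery — moves to a background factor in
species B (module shift).  Venom-flagged genes receive >= 3 synthetic
proteomic peptides; everything else receives none.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["gen_expression_pair", "STAGES"]

STAGES = ["L2", "L3", "L4", "FP", "MP", "FA", "MA", "venom_gland", "carcass"]
N_BACKGROUND_FACTORS = 5
VG_INDEX = STAGES.index("venom_gland")
VG_PEAK_TPM = 400.0


def _factor_profiles() -> np.ndarray:
    """(n_factors, n_stages) mean TPM profiles; factor 0 is the venom factor,
    high only in the venom gland."""
    profiles = np.full((1 + N_BACKGROUND_FACTORS, len(STAGES)), 2.0)
    profiles[0, VG_INDEX] = VG_PEAK_TPM
    for k in range(N_BACKGROUND_FACTORS):
        row = profiles[k + 1]
        row[:] = 5.0
        row[k % 7] = 60.0
        row[(k + 3) % 7] = 60.0
        row[STAGES.index("carcass")] = 15.0
        row[VG_INDEX] = 8.0
    return profiles


def gen_expression_pair(
    n_genes: int = 1000,
    n_samples: int = 27,
    venom_module_size: int = 60,
    shift_set_size: int = 6,
    noise_sd: float = 0.3,
    seed: int = 0,
    module_shift_size: int = 18,
    venom_fraction: float = 0.4,
) -> dict:
    """Simulate paired expression matrices with planted venom-module structure.

    Parameters
    ----------
    n_samples : total samples per species; replicates are spread evenly
        over the nine stage/tissue labels.
    venom_module_size : planted venom-module size (>= 30, the module-caller
        minimum).
    shift_set_size : venom genes of species A whose orthologs lose
        venom-gland expression in species B.
    noise_sd : heteroscedastic noise scale (sd = noise_sd * sqrt(mean + 1)
    TPM); 0 gives exact mixture profiles.
    module_shift_size : peripheral non-venom module members reassigned to a
        background factor in species B.
    venom_fraction : fraction of the module that is venom-flagged (peptide
        supported).

    Returns a dict with ``expr_a``/``expr_b`` (genes x samples TPM),
    ``sample_labels``, ``ortholog_map`` (A gene -> B gene), ``peptides_a``/
    ``peptides_b`` and a ``truth`` record of every planted set.
    """
    if venom_module_size < 30:
        raise ValueError("venom_module_size must be >= 30")
    if venom_module_size > n_genes:
        raise ValueError("venom module larger than gene count")
    if shift_set_size > n_genes:
        raise ValueError("shift_set_size exceeds n_genes")
    n_venom = int(round(venom_fraction * venom_module_size))
    if shift_set_size > n_venom:
        raise ValueError("shift_set_size exceeds the venom-flagged module part")
    if module_shift_size > venom_module_size - n_venom:
        raise ValueError("module_shift_size exceeds the non-venom module part")
    if venom_module_size - shift_set_size - module_shift_size < 30:
        raise ValueError(
            "planted reassignments leave the species-B venom module below the "
            "module-caller minimum of 30 genes"
        )

    rng = np.random.default_rng(seed)
    profiles = _factor_profiles()

    reps = [n_samples // len(STAGES)] * len(STAGES)
    for i in range(n_samples - sum(reps)):
        reps[i] += 1
    samples, stage_of = [], {}
    for stage, r in zip(STAGES, reps):
        for j in range(r):
            name = f"{stage}_r{j + 1}"
            samples.append(name)
            stage_of[name] = stage
    stage_idx = np.array([STAGES.index(stage_of[s]) for s in samples])

    genes_a = [f"gA{i:06d}" for i in range(n_genes)]
    genes_b = [f"gB{i:06d}" for i in range(n_genes)]

    module = list(range(venom_module_size))
    # mixing weight = true connectivity; shared by the ortholog pair.  The
    # venom module spans hubs to periphery (0.3-0.95); background factors
    # use a narrower, well-connected range.
    loadings = rng.uniform(0.55, 0.95, size=n_genes)
    loadings[:venom_module_size] = rng.uniform(0.3, 0.95, size=venom_module_size)
    # gene-private stage profiles, shared by the ortholog pair; the venom
    # gland stays quiet so only the venom factor drives VG expression
    private = rng.uniform(2.0, 60.0, size=(n_genes, len(STAGES)))
    private[:, VG_INDEX] = rng.uniform(2.0, 8.0, size=n_genes)

    factor_a = np.empty(n_genes, dtype=int)
    factor_a[:venom_module_size] = 0
    factor_a[venom_module_size:] = 1 + (
        rng.integers(0, N_BACKGROUND_FACTORS, size=n_genes - venom_module_size)
    )

    venom_idx = module[:n_venom]
    nonvenom_module = module[n_venom:]
    shift_idx = list(rng.choice(venom_idx, size=shift_set_size, replace=False))
    # module shifts planted in the module periphery: lowest-connectivity members
    periphery = sorted(nonvenom_module, key=lambda i: loadings[i])
    module_shift_idx = periphery[:module_shift_size]

    factor_b = factor_a.copy()
    reassign = shift_idx + module_shift_idx
    factor_b[reassign] = 1 + (
        rng.integers(0, N_BACKGROUND_FACTORS, size=len(reassign))
    )

    def _matrix(factor: np.ndarray, gene_ids: list[str]) -> pd.DataFrame:
        lam = loadings[:, None]
        mean = lam * profiles[factor][:, stage_idx] + (1.0 - lam) * private[
            :, stage_idx
        ]
        noise = rng.normal(0.0, noise_sd, size=mean.shape) * np.sqrt(mean + 1.0)
        tpm = np.clip(mean + noise, 0.0, None)
        return pd.DataFrame(tpm, index=gene_ids, columns=samples)

    expr_a = _matrix(factor_a, genes_a)
    expr_b = _matrix(factor_b, genes_b)

    venom_a = [genes_a[i] for i in venom_idx]
    venom_b = [genes_b[i] for i in venom_idx if i not in shift_idx]
    peptides_a = {g: int(rng.integers(3, 15)) for g in venom_a}
    peptides_b = {g: int(rng.integers(3, 15)) for g in venom_b}

    truth = {
        "module_genes_a": [genes_a[i] for i in module],
        "module_genes_b": [genes_b[i] for i in module if i not in reassign],
        "venom_genes_a": venom_a,
        "venom_genes_b": venom_b,
        "shift_set_a": [genes_a[i] for i in shift_idx],
        "module_shift_a": [genes_a[i] for i in module_shift_idx],
        "loadings": {genes_a[i]: float(loadings[i]) for i in range(n_genes)},
        "factor_a": {genes_a[i]: int(factor_a[i]) for i in range(n_genes)},
        "factor_b": {genes_b[i]: int(factor_b[i]) for i in range(n_genes)},
    }
    return {
        "expr_a": expr_a,
        "expr_b": expr_b,
        "sample_labels": stage_of,
        "ortholog_map": dict(zip(genes_a, genes_b)),
        "peptides_a": peptides_a,
        "peptides_b": peptides_b,
        "truth": truth,
    }
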