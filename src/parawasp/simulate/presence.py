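"""Binary presence/absence matrices over a dated species tree.

Each orthogroup is gained on a named node of the species tree and is
present in every descendant species except independent losses drawn per
tip with a fixed probability, giving Wagner-parsimony dating a known
ground-truth gain node.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import dendropy

from ..trees import find_node, node_name

__all__ = ["gen_presence_absence"]


def gen_presence_absence(
    species_tree: dendropy.Tree,
    gain_node: str,
    loss_prob: float,
    n_ogs: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate orthogroup presence/absence with a known gain node.

    Presence is planted in all species descending from ``gain_node`` (a
    node label, or a species name for terminal gains), then each of those
    tips loses the orthogroup independently with probability ``loss_prob``
    (< 0.5).  All-absent draws are rejected and redrawn so every orthogroup
    stays datable.  Returns (matrix ogs x species, ground_truth).
    """
    if not 0.0 <= loss_prob < 0.5:
        raise ValueError("loss_prob must lie in [0, 0.5)")
    if n_ogs < 0:
        raise ValueError("n_ogs must be non-negative")
    node = find_node(species_tree, gain_node)  # KeyError if absent
    rng = np.random.default_rng(seed)

    species = [t.label for t in species_tree.taxon_namespace]
    descendants = [leaf.taxon.label for leaf in node.leaf_iter()]
    rows = {}
    for i in range(n_ogs):
        while True:
            losses = rng.random(len(descendants)) < loss_prob
            if not losses.all():
                break
        row = {sp: 0 for sp in species}
        for sp, lost in zip(descendants, losses):
            row[sp] = 0 if lost else 1
        rows[f"OG{i:06d}"] = row
    matrix = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
    matrix = matrix.reindex(columns=species) if n_ogs else pd.DataFrame(
        columns=species, dtype=int
    )
    truth = {"gain_node": gain_node, "loss_prob": loss_prob}
    return matrix, truth
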