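"""Gene trees realising the four venom-origin scenarios.

Topologies are built on the default 20-taxon species-tree backbone
(19 hymenopterans + a dipteran outgroup) and are species-tree-consistent,
so the species-overlap duplication rule and LCA reconciliation agree on
them.  Leaf labels are ``Species|tag`` with tags distinguishing paralog
copies; venom flags mark the *Anastatus* leaves of the recruited copy.
"""

from __future__ import annotations

import numpy as np

from ..trees import DEFAULT_ANASTATUS, DEFAULT_CHALCIDOIDEA, load_tree

__all__ = ["SCENARIOS", "gen_gene_trees"]

SCENARIOS = (
    "single_copy",
    "ancient_dup",
    "chalcid_dup",
    "dup_neofunctionalization",
)

EXPECTED_MODEL = {
    "single_copy": "single_copy_cooption",
    "ancient_dup": "ancient_dup_cooption",
    "chalcid_dup": "chalcid_dup_cooption",
    "dup_neofunctionalization": "dup_neofunctionalization",
}

AJAP = "Anastatus_japonicus"
AFUL = "Anastatus_fulloi"

_ANASTATUS_TOPO = (AJAP, AFUL)
_CHALCID_TOPO = (
    "Trichogramma_pretiosum",
    (
        "Ceratosolen_solmsi",
        (
            "Copidosoma_floridanum",
            (
                "Encarsia_formosa",
                (("Nasonia_vitripennis", "Pteromalus_puparum"), _ANASTATUS_TOPO),
            ),
        ),
    ),
)
_TOPOLOGY = (
    "Athalia_rosae",
    (
        "Orussus_abietinus",
        (
            ("Cephus_cinctus", ("Microplitis_demolitor", "Macrocentrus_cingulum")),
            (
                (
                    ("Apis_mellifera", "Bombus_terrestris"),
                    (
                        "Polistes_dominula",
                        ("Solenopsis_invicta", "Harpegnathos_saltator"),
                    ),
                ),
                (_CHALCID_TOPO, "Gonatopus_flavifemur"),
            ),
        ),
    ),
)


def _leaves(node) -> list[str]:
    if isinstance(node, str):
        return [node]
    out = []
    for child in node:
        out.extend(_leaves(child))
    return out

ALL_SPECIES = _leaves(_TOPOLOGY)
_OUTGROUPS = [s for s in ALL_SPECIES if s not in DEFAULT_CHALCIDOIDEA]
_CHALCID_NONANA = [
    s for s in DEFAULT_CHALCIDOIDEA if s not in DEFAULT_ANASTATUS
]


def _prune(node, keep: set[str]):
    """Restrict a nested-tuple topology to ``keep``; None if nothing remains."""
    if isinstance(node, str):
        return node if node in keep else None
    kept = [c for c in (_prune(child, keep) for child in node) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    return tuple(kept)


_GRAFT = "@GRAFT@"


def _replace(node, target):
    """Substitute the subtree ``target`` (by identity) with a graft marker."""
    if node is target:
        return _GRAFT
    if isinstance(node, str):
        return node
    return tuple(_replace(child, target) for child in node)


def _newick(node, tag: str, graft: str | None = None) -> str:
    """Render a topology to newick, labelling leaves ``Species|tag``.

    A ``@GRAFT@`` marker leaf is replaced by the pre-rendered newick string
    ``graft`` (used to splice duplicated clades into the backbone).
    """
    if isinstance(node, str):
        if node == _GRAFT:
            if graft is None:
                raise ValueError("graft marker present but no graft supplied")
            return graft
        return f"'{node}|{tag}':1"
    inner = ",".join(_newick(child, tag, graft) for child in node)
    return f"({inner}):1"


def _random_keep(rng: np.random.Generator) -> set[str]:
    """Random species retention: both Anastatus, two Pteromalidae anchors,
    at least two outgroups, plus random extras."""
    keep = {AJAP, AFUL, "Nasonia_vitripennis", "Pteromalus_puparum"}
    outs = list(rng.choice(_OUTGROUPS, size=2, replace=False))
    keep.update(outs)
    for sp in ALL_SPECIES:
        if sp not in keep and rng.random() < 0.4:
            keep.add(sp)
    return keep


def _build(scenario: str, rng: np.random.Generator) -> dict:
    if scenario == "single_copy":
        keep = _random_keep(rng)
        nwk = _newick(_prune(_TOPOLOGY, keep), "g1") + ";"
        venom = {f"{AJAP}|g1", f"{AFUL}|g1"}
    elif scenario == "ancient_dup":
        keep2 = _random_keep(rng)
        # the sister copy shares the outgroups (species overlap => duplication)
        keep1 = {s for s in keep2 if s not in DEFAULT_ANASTATUS}
        copy1 = _newick(_prune(_TOPOLOGY, keep1), "c1")
        copy2 = _newick(_prune(_TOPOLOGY, keep2), "c2")
        nwk = f"({copy1},{copy2});"
        venom = {f"{AJAP}|c2", f"{AFUL}|c2"}
    elif scenario == "chalcid_dup":
        keep = _random_keep(rng)
        chal_keep2 = {s for s in keep if s in DEFAULT_CHALCIDOIDEA}
        chal_keep1 = {s for s in chal_keep2 if s not in DEFAULT_ANASTATUS}
        copy1 = _newick(_prune(_CHALCID_TOPO, chal_keep1), "c1")
        copy2 = _newick(_prune(_CHALCID_TOPO, chal_keep2), "c2")
        grafted = f"({copy1},{copy2}):1"
        backbone = _prune(
            _replace(_TOPOLOGY, _CHALCID_TOPO), keep | {_GRAFT}
        )
        nwk = _newick(backbone, "g1", graft=grafted) + ";"
        venom = {f"{AJAP}|c2", f"{AFUL}|c2"}
    elif scenario == "dup_neofunctionalization":
        keep = _random_keep(rng)
        if rng.random() < 0.7:
            # duplication in the Anastatus ancestor, one copy recruited
            grafted = (
                f"(('{AJAP}|c1':1,'{AFUL}|c1':1):1,"
                f"('{AJAP}|c2':1,'{AFUL}|c2':1):1):1"
            )
            venom = {f"{AJAP}|c2", f"{AFUL}|c2"}
        else:
            # species-specific duplication in A. japonicus
            grafted = (
                f"(('{AJAP}|c1':1,'{AJAP}|c2':1):1,'{AFUL}|c1':1):1"
            )
            venom = {f"{AJAP}|c2"}
        backbone = _prune(
            _replace(_TOPOLOGY, _ANASTATUS_TOPO), keep | {_GRAFT}
        )
        nwk = _newick(backbone, "g1", graft=grafted) + ";"
    else:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")

    tree = load_tree(nwk)
    species_map = {
        leaf.taxon.label: leaf.taxon.label.split("|")[0]
        for leaf in tree.leaf_node_iter()
    }
    return {
        "newick": nwk,
        "tree": tree,
        "species_map": species_map,
        "venom_leaves": venom,
    }


def gen_gene_trees(
    scenario: str, n_trees: int = 1, seed: int = 0
) -> tuple[list[dict], dict]:
    """Generate gene trees realising one venom-origin scenario.

    Returns (trees, ground_truth): each tree record carries the newick
    string, a parsed dendropy tree, the leaf -> species map and the venom
    leaf set; ground truth states the origin model the classifier should
    recover for every venom leaf.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if n_trees < 0:
        raise ValueError("n_trees must be non-negative")
    rng = np.random.default_rng(seed)
    trees = [_build(scenario, rng) for _ in range(n_trees)]
    truth = {"scenario": scenario, "expected_model": EXPECTED_MODEL[scenario]}
    return trees, truth
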