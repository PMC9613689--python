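"""Dated species-tree utilities shared by the ancestral-state and gene-tree code.

Trees are dendropy objects throughout.  A "dated" tree is ultrametric with
branch lengths in My; node ages are recovered from root-to-tip depths.
"""

from __future__ import annotations

import dendropy

__all__ = [
    "load_tree",
    "node_ages",
    "node_name",
    "find_node",
    "leaf_species",
    "default_species_tree",
    "DEFAULT_CHALCIDOIDEA",
    "DEFAULT_ANASTATUS",
]

ULTRAMETRIC_TOL = 1e-6


def load_tree(source: str, *, is_path: bool = False) -> dendropy.Tree:
    """Read a rooted Newick tree from a string or file path."""
    kwargs = {"path" if is_path else "data": source, "schema": "newick"}
    tree = dendropy.Tree.get(preserve_underscores=True, **kwargs)
    tree.is_rooted = True
    return tree


def node_name(node: dendropy.Node) -> str:
    """Taxon label for leaves, node label for internal nodes ('' if unnamed)."""
    if node.taxon is not None:
        return node.taxon.label
    return node.label or ""


def node_ages(tree: dendropy.Tree, tol: float = ULTRAMETRIC_TOL) -> dict[dendropy.Node, float]:
    """Age of every node (My before present) of an ultrametric tree.

    Raises ``ValueError`` if root-to-tip depths differ by more than ``tol``
    relative to the tree height.
    """
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    tip_depths = [depths[leaf] for leaf in tree.leaf_node_iter()]
    height = max(tip_depths)
    if height > 0 and (height - min(tip_depths)) / height > tol:
        raise ValueError(
            f"tree is not ultrametric: tip depths span "
            f"[{min(tip_depths):.6g}, {height:.6g}]"
        )
    return {node: height - depth for node, depth in depths.items()}


def find_node(tree: dendropy.Tree, name: str) -> dendropy.Node:
    """Locate a node by taxon label (leaf) or node label (internal)."""
    for node in tree.preorder_node_iter():
        if node_name(node) == name:
            return node
    raise KeyError(f"node {name!r} not found in tree")


def leaf_species(node: dendropy.Node) -> frozenset[str]:
    """Set of leaf taxon labels below (and including) ``node``."""
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


# A 19-taxon dated hymenopteran phylogeny used as the default simulation
# backdrop: two Anastatus species (Eupelmidae) nested inside Chalcidoidea,
# with sawfly/wasp/ant/bee outgroups.  Node ages (My) follow published
# calibration ranges for the named clades; unnamed ages are plausible
# interpolations.  Internal labels: Anastatus_ANC (Anastatus ancestor),
# EPA (Eupelmidae + Pteromalidae ancestor), CA (Chalcidoidea ancestor).
_DEFAULT_TREE_NEWICK = (
    "((Athalia_rosae:250,(Orussus_abietinus:240,((Cephus_cinctus:220,"
    "(Microplitis_demolitor:60,Macrocentrus_cingulum:60)Braconidae:160)"
    ":10,(((Apis_mellifera:100,Bombus_terrestris:100)Apidae:80,"
    "(Polistes_dominula:150,(Solenopsis_invicta:120,Harpegnathos_saltator:120)"
    "Formicidae:30)Aculeata_core:30)Aculeata:20,((Trichogramma_pretiosum:105,"
    "(Ceratosolen_solmsi:100,(Copidosoma_floridanum:95,(Encarsia_formosa:92,"
    "((Nasonia_vitripennis:30,Pteromalus_puparum:30)Pteromalidae:48,"
    "(Anastatus_japonicus:3,Anastatus_fulloi:3)Anastatus_ANC:75)EPA:14)"
    ":3):5):5)CA:50,Gonatopus_flavifemur:155)Chalcid_lineage:45)Apocrita:30"
    ")Apocrita_stem:10)Orussoidea_Apocrita:10)Hymenoptera:0,"
    "Drosophila_melanogaster:250)Root:0;"
)

DEFAULT_CHALCIDOIDEA = frozenset(
    {
        "Trichogramma_pretiosum",
        "Ceratosolen_solmsi",
        "Copidosoma_floridanum",
        "Encarsia_formosa",
        "Nasonia_vitripennis",
        "Pteromalus_puparum",
        "Anastatus_japonicus",
        "Anastatus_fulloi",
    }
)

DEFAULT_ANASTATUS = frozenset({"Anastatus_japonicus", "Anastatus_fulloi"})


def default_species_tree() -> dendropy.Tree:
    """The default 19-taxon dated species tree (fresh copy per call)."""
    return load_tree(_DEFAULT_TREE_NEWICK)
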