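"""Cross-species venom orthogroup comparison, recruitment dating and
origin-model classification.

Venom recruitment age is reconstructed by Wagner parsimony: the binary
presence/absence of an orthogroup over a dated species tree is mapped onto
ancestral nodes under equal gain/loss costs (Sankoff dynamic programming),
and the recruitment age is the oldest node reconstructed as present, with
ties resolved toward the older node (gain-early preference).

Each venom gene's evolutionary origin is classified into one of four
models by locating the most recent duplication node on its root path in a
species-overlap-annotated gene tree:

1. ``single_copy_cooption``    — no duplication, orthogroup single-copy in
   every species: a universal single-copy gene co-opted into venom.
2. ``ancient_dup_cooption``    — the duplication predates Chalcidoidea
   (its species span includes non-chalcid species).
3. ``chalcid_dup_cooption``    — the duplication lies inside Chalcidoidea
   but predates the *Anastatus* divergence.
4. ``dup_neofunctionalization`` — a recent *Anastatus*-restricted
   duplication with at least one non-venom paralog.

Genes matching no predicate are ``unclassified``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

from .trees import leaf_species, node_ages, node_name

__all__ = [
    "OrthoGroup",
    "ORIGIN_MODELS",
    "compare_venom_ogs",
    "filter_ogs",
    "wagner_age",
    "infer_duplication_nodes",
    "classify_venom_origin",
]

ORIGIN_MODELS = (
    "single_copy_cooption",
    "ancient_dup_cooption",
    "chalcid_dup_cooption",
    "dup_neofunctionalization",
    "unclassified",
)


@dataclass
class OrthoGroup:
    """An orthogroup: (species, gene_id) members with per-gene venom flags."""

    og_id: str
    members: list[tuple[str, str]]
    venom: set[str] = field(default_factory=set)

    def species_set(self) -> frozenset[str]:
        return frozenset(sp for sp, _ in self.members)

    def venom_count(self, species: str) -> int:
        return sum(1 for sp, g in self.members if sp == species and g in self.venom)

    def copy_count(self, species: str) -> int:
        return sum(1 for sp, _ in self.members if sp == species)


def compare_venom_ogs(
    ogs: Iterable[OrthoGroup], species_a: str, species_b: str
) -> dict[str, list[str]]:
    """Partition venom orthogroups of a species pair.

    Returns og_id lists: ``shared`` (venom genes in both species),
    ``a_specific`` / ``b_specific`` (venom in one), and
    ``strictly_conserved`` — the shared subset with identical venom-gene
    copy number in the two species.
    """
    shared, a_only, b_only, strict = [], [], [], []
    for og in ogs:
        va, vb = og.venom_count(species_a), og.venom_count(species_b)
        if va == 0 and vb == 0:
            continue
        if va and vb:
            shared.append(og.og_id)
            if va == vb:
                strict.append(og.og_id)
        elif va:
            a_only.append(og.og_id)
        else:
            b_only.append(og.og_id)
    return {
        "shared": shared,
        "a_specific": a_only,
        "b_specific": b_only,
        "strictly_conserved": strict,
    }


def filter_ogs(
    ogs: Iterable[OrthoGroup],
    focal_species: frozenset[str] | set[str],
    min_members: int = 5,
) -> list[OrthoGroup]:
    """Drop orthogroups restricted to the focal clade or with < 5 members —
    both give ambiguous gene trees."""
    kept = []
    for og in ogs:
        if og.species_set() <= frozenset(focal_species):
            continue
        if len(og.members) < min_members:
            continue
        kept.append(og)
    return kept


def wagner_age(
    presence: Mapping[str, int], species_tree: dendropy.Tree
) -> dendropy.Node:
    """Oldest node reconstructed as present under equal-cost Wagner parsimony.

    ``presence`` maps species (taxon labels) to 0/1; species missing from
    the mapping count as absent.  State ties during the reconstruction are
    resolved toward presence, which realises the gain-early preference.

    Returns the dendropy node (a leaf for species-specific genes, the root
    for ubiquitous ones).  Raises ``ValueError`` on an all-absent vector.
    """
    if not any(presence.get(t.label, 0) for t in species_tree.taxon_namespace):
        raise ValueError("presence vector is all-absent")

    INF = float("inf")
    cost: dict[dendropy.Node, list[float]] = {}
    for node in species_tree.postorder_node_iter():
        if node.is_leaf():
            state = int(presence.get(node.taxon.label, 0))
            cost[node] = [INF, INF]
            cost[node][state] = 0.0
        else:
            c = [0.0, 0.0]
            for child in node.child_nodes():
                for s in (0, 1):
                    c[s] += min(cost[child][t] + (s != t) for t in (0, 1))
            cost[node] = c

    state: dict[dendropy.Node, int] = {}
    for node in species_tree.preorder_node_iter():
        if node.parent_node is None:
            c0, c1 = cost[node]
            state[node] = 1 if c1 <= c0 else 0
        else:
            ps = state[node.parent_node]
            c0 = cost[node][0] + (ps != 0)
            c1 = cost[node][1] + (ps != 1)
            state[node] = 1 if c1 <= c0 else 0

    ages = node_ages(species_tree)
    present = [n for n in species_tree.preorder_node_iter() if state[n] == 1]
    return max(present, key=lambda n: ages[n])


def infer_duplication_nodes(
    gene_tree: dendropy.Tree, species_map: Mapping[str, str]
) -> dict[dendropy.Node, str]:
    """Label internal nodes speciation/duplication by the species-overlap rule.

    A node is a duplication iff the species sets of its child clades
    intersect.  ``species_map`` maps gene-tree leaf labels to species names.
    Mechanises the manual screen usually applied to venom orthogroup trees;
    it agrees with LCA reconciliation on species-tree-consistent topologies.
    """
    if not gene_tree.is_rooted:
        raise ValueError(
            "gene tree must be rooted (midpoint- or outgroup-root it first)"
        )
    species_below: dict[dendropy.Node, frozenset[str]] = {}
    events: dict[dendropy.Node, str] = {}
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in species_map:
                raise KeyError(f"leaf {label!r} missing from species_map")
            species_below[node] = frozenset({species_map[label]})
        else:
            children = node.child_nodes()
            species_below[node] = frozenset().union(
                *(species_below[c] for c in children)
            )
            overlap = False
            for i, a in enumerate(children):
                for b in children[i + 1 :]:
                    if species_below[a] & species_below[b]:
                        overlap = True
            events[node] = "duplication" if overlap else "speciation"
    return events


def classify_venom_origin(
    gene_tree: dendropy.Tree,
    species_map: Mapping[str, str],
    venom_leaves: set[str],
    chalcidoidea: frozenset[str] | set[str],
    anastatus: frozenset[str] | set[str],
    events: Mapping[dendropy.Node, str] | None = None,
) -> dict[str, str]:
    """Classify each venom leaf into one of the four origin models.

    ``venom_leaves`` are gene-tree leaf labels flagged as venom genes;
    ``chalcidoidea`` / ``anastatus`` are the clade species sets.  Returns
    leaf label -> model name.
    """
    chalcidoidea = frozenset(chalcidoidea)
    anastatus = frozenset(anastatus)
    if events is None:
        events = infer_duplication_nodes(gene_tree, species_map)

    leaves = {n.taxon.label: n for n in gene_tree.leaf_node_iter()}
    missing = venom_leaves - leaves.keys()
    if missing:
        raise ValueError(f"venom leaves absent from gene tree: {sorted(missing)[:5]}")

    copy_counts: dict[str, int] = {}
    for label in leaves:
        sp = species_map[label]
        copy_counts[sp] = copy_counts.get(sp, 0) + 1
    single_copy_everywhere = all(c == 1 for c in copy_counts.values())

    def species_span(node: dendropy.Node) -> frozenset[str]:
        return frozenset(species_map[l.taxon.label] for l in node.leaf_iter())

    calls: dict[str, str] = {}
    for label in sorted(venom_leaves):
        node = leaves[label].parent_node
        dup = None
        while node is not None:
            if events.get(node) == "duplication":
                dup = node
                break
            node = node.parent_node
        if dup is None:
            calls[label] = (
                "single_copy_cooption" if single_copy_everywhere else "unclassified"
            )
            continue
        span = species_span(dup)
        if span - chalcidoidea:
            calls[label] = "ancient_dup_cooption"
        elif span - anastatus:
            calls[label] = "chalcid_dup_cooption"
        else:
            has_nonvenom_paralog = any(
                l.taxon.label not in venom_leaves for l in dup.leaf_iter()
            )
            calls[label] = (
                "dup_neofunctionalization" if has_nonvenom_paralog else "unclassified"
            )
    return calls
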