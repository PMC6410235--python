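"""Species trees and Dollo placement of shared mutations.

Identical left-normalized mutation calls from different species are
grouped by exact key and assigned, under a single-origin/no-reversal
(Dollo) assumption, to the branch above the most recent common ancestor
of the carrier species. Descendants of that ancestor that carry usable
data but lack the mutation are reported as conflicts (possible
independent origin or missed call) rather than silently accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from .mutations import MutationCall

__all__ = [
    "SpeciesTree",
    "SharedMutationGroup",
    "parse_newick",
    "match_mutations",
    "assign_to_branch",
]


class NewickError(ValueError):
    pass


@dataclass
class SpeciesTree:
    """Rooted species tree with unique leaf labels."""

    tree: dendropy.Tree

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def mrca(self, labels: set[str]) -> dendropy.Node:
        if not labels:
            raise ValueError("empty label set")
        missing = labels - set(self.leaf_labels)
        if missing:
            raise KeyError(f"unknown species: {sorted(missing)}")
        if len(labels) == 1:
            (label,) = labels
            return self.tree.find_node_with_taxon_label(label)
        return self.tree.mrca(taxon_labels=sorted(labels))

    def node_name(self, node: dendropy.Node) -> str:
        if node.taxon is not None:
            return node.taxon.label
        if node.label:
            return node.label
        leaves = sorted(l.taxon.label for l in node.leaf_iter())
        return "{" + ",".join(leaves) + "}"

    def leaves_under(self, node: dendropy.Node) -> set[str]:
        return {l.taxon.label for l in node.leaf_iter()}


def parse_newick(text: str) -> SpeciesTree:
    """Parse a rooted newick string, preserving internal node labels."""
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickError(f"unbalanced ')' at position {i}")
    if depth != 0:
        raise NewickError(f"unbalanced '(' ({depth} unclosed) in newick text")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"newick parse error: {exc}") from exc
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise NewickError("duplicate leaf labels")
    return SpeciesTree(tree=tree)


@dataclass
class SharedMutationGroup:
    """One mutation shared by descent (or convergence) across species."""

    key: tuple
    carriers: set[str]
    indeterminate: set[str] = field(default_factory=set)
    assigned_branch: str | None = None
    conflicts: set[str] = field(default_factory=set)
    calls: list[MutationCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = self.carriers & self.indeterminate
        if overlap:
            raise ValueError(f"species both carrier and indeterminate: {overlap}")


def match_mutations(
    calls_by_species: dict[str, list[MutationCall]],
    indeterminate_by_species: dict[str, set[tuple]] | None = None,
    stop_codon_tolerance: int = 0,
) -> list[SharedMutationGroup]:
    """Group identical calls across species by exact key.

    ``indeterminate_by_species`` maps species to keys (or
    ``(gene, exon_index)`` pairs) at which the species has no usable data
    (exon in an assembly gap): those species join the group as
    indeterminate rather than absent. Calls flagged as frameshift
    consequences are excluded. An optional ±``stop_codon_tolerance``
    codons of positional slack applies to premature stops only
    (default off).
    """
    groups: dict[tuple, SharedMutationGroup] = {}
    for species, calls in calls_by_species.items():
        for call in calls:
            if call.frameshift_context:
                continue
            key = call.key
            if key not in groups:
                groups[key] = SharedMutationGroup(key=key, carriers=set())
            groups[key].carriers.add(species)
            groups[key].calls.append(call)
    if stop_codon_tolerance:
        _merge_nearby_stops(groups, stop_codon_tolerance)
    indet = indeterminate_by_species or {}
    for species, marks in indet.items():
        for key, group in groups.items():
            gene, _type, exon_index = key[0], key[1], key[2]
            if species in group.carriers:
                continue
            if key in marks or (gene, exon_index) in marks:
                group.indeterminate.add(species)
    return sorted(groups.values(), key=lambda g: (g.key[0], g.key[3], g.key[1]))


def _merge_nearby_stops(
    groups: dict[tuple, SharedMutationGroup], tol_codons: int
) -> None:
    stops = [k for k in groups if k[1] == "premature_stop"]
    stops.sort(key=lambda k: (k[0], k[2], k[3]))
    for a, b in zip(stops, stops[1:]):
        if a[0] == b[0] and a[2] == b[2] and abs(a[3] - b[3]) <= 3 * tol_codons:
            if b in groups and a in groups:
                groups[a].carriers |= groups[b].carriers
                groups[a].calls += groups[b].calls
                del groups[b]


def assign_to_branch(
    group: SharedMutationGroup, species_tree: SpeciesTree
) -> str:
    """Dollo placement: the branch above the MRCA of the carriers.

    Mutates ``group`` in place, setting ``assigned_branch`` to the MRCA
    node's name and ``conflicts`` to non-carrier, non-indeterminate
    descendant species of that node. Returns the branch name.
    """
    if not group.carriers:
        raise ValueError("carriers non-empty required")
    unknown = group.carriers - set(species_tree.leaf_labels)
    if unknown:
        raise KeyError(f"unknown species: {sorted(unknown)}")
    mrca = species_tree.mrca(group.carriers)
    group.assigned_branch = species_tree.node_name(mrca)
    descendants = species_tree.leaves_under(mrca)
    group.conflicts = descendants - group.carriers - group.indeterminate
    return group.assigned_branch


def group_summary_rows(groups: list[SharedMutationGroup]) -> list[dict]:
    rows = []
    for g in groups:
        gene, mtype, exon, cds_pos, length, alt = g.key
        rows.append(
            {
                "gene": gene,
                "type": mtype,
                "exon": exon + 1,
                "cds_pos": cds_pos + 1,
                "length": length,
                "alt": alt,
                "carriers": ",".join(sorted(g.carriers)),
                "n_carriers": len(g.carriers),
                "indeterminate": ",".join(sorted(g.indeterminate)),
                "branch": g.assigned_branch or ".",
                "conflicts": ",".join(sorted(g.conflicts)) or ".",
            }
        )
    return rows
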