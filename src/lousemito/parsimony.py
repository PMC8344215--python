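"""Two-rule parsimony reconstruction of an ancestral mitochondrial karyotype.

The procedure reconstructs the karyotype at the most recent common ancestor
(MRCA) of a designated ingroup on a fixed rooted phylogeny:

1. A placement (character state) is a *candidate* ancestral state if it is
   present in at least one ingroup taxon **and** in at least one taxon outside
   the ingroup (rule 1), or if it is present in **all** ingroup taxa with data
   (rule 2).  Taxa without data (NA) do not vote.
2. When candidates conflict, the one requiring the fewest state changes on
   the ingroup subtree (with the candidate fixed at the MRCA node) wins;
   exact ties are reported as equally parsimonious alternatives, never broken
   silently.

Backbone characters are resolved first; tRNA placements are then resolved
conditional on the ancestral backbone set.  Change counts use an unordered
state alphabet (any placement can turn into any other in one step), computed
by Sankoff dynamic programming with the root state fixed.

When neither rule admits a candidate for a unit -- which happens when every
observed placement is private to a proper subset of the ingroup -- the
observed ingroup placements compete directly on change count.  This fallback
is what yields the published equally-parsimonious S1-S2 alternatives in the
*Polyplax* reconstruction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy

from .characters import NA, CharacterState, extract_characters
from .genes import NCR
from .karyotype import (
    BackboneKey,
    Karyotype,
    KaryotypeError,
    Minichromosome,
    OrientedGene,
)
from .genes import GeneSymbol

# ---------------------------------------------------------------------------
# Tree handling


@dataclass
class PhylogenyTree:
    """A rooted tree with uniquely labelled leaves; genus = label prefix."""

    tree: dendropy.Tree

    @classmethod
    def from_newick(cls, text: str) -> "PhylogenyTree":
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
        tree.is_rooted = True
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels must be unique")
        return cls(tree)

    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @staticmethod
    def genus_of(label: str) -> str:
        return label.split("_")[0].split(" ")[0]

    def mrca(self, taxa: set[str]) -> dendropy.Node:
        return self.tree.mrca(taxon_labels=sorted(taxa))

    def ingroup_is_monophyletic(self, taxa: set[str]) -> bool:
        node = self.mrca(taxa)
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        return below == set(taxa)


def sankoff_changes(
    node: dendropy.Node,
    tip_states: dict[str, object],
    root_state: object,
    alphabet: list[object],
) -> int:
    """Minimal number of state changes on the subtree rooted at ``node``
    with the root's state fixed, unit change costs, NA tips free.

    Tips absent from ``tip_states`` (or mapped to NA) contribute zero cost in
    every state, i.e. they are treated as missing data.
    """
    INF = 10**9

    def costs(n: dendropy.Node) -> list[int]:
        if n.is_leaf():
            label = n.taxon.label
            state = tip_states.get(label, NA)
            if state == NA:
                return [0] * len(alphabet)
            if state not in alphabet:
                return [INF] * len(alphabet)
            return [0 if s == state else INF for s in alphabet]
        child_costs = [costs(c) for c in n.child_nodes()]
        out = []
        for i in range(len(alphabet)):
            total = 0
            for cc in child_costs:
                total += min(
                    cc[j] + (0 if j == i else 1) for j in range(len(alphabet))
                )
            out.append(total)
        return out

    if root_state not in alphabet:
        raise ValueError("root state must be in the alphabet")
    return costs(node)[alphabet.index(root_state)]


def parsimony_changes(
    tree: PhylogenyTree,
    character: CharacterState,
    candidate: object,
    ingroup: set[str],
) -> int:
    """Change count for ``candidate`` fixed at the ingroup's MRCA node."""
    states = {t: s for t, s in character.states if t in ingroup and s != NA}
    alphabet = sorted({candidate, *states.values()}, key=repr)
    node = tree.mrca(set(ingroup))
    return sankoff_changes(node, states, candidate, alphabet)


# ---------------------------------------------------------------------------
# Candidate rules


def candidate_states(
    character: CharacterState,
    ingroup: set[str],
    extra_outgroup_states: tuple[object, ...] = (),
) -> set[object]:
    """Apply the two candidacy rules to one character.

    ``extra_outgroup_states`` carries outgroup-side evidence from reference
    karyotypes that are not leaves of the tree (they vote in rule 1 only).
    Raises on an all-NA character.
    """
    if not character.informative and not extra_outgroup_states:
        raise ValueError(f"uninformative character: {character.unit}")
    in_states = [s for t, s in character.states if t in ingroup and s != NA]
    out_states = [s for t, s in character.states if t not in ingroup and s != NA]
    out_states += [s for s in extra_outgroup_states if s != NA]
    candidates: set[object] = set()
    for s in set(in_states):
        if s in out_states:  # rule 1
            candidates.add(s)
        elif in_states and all(x == s for x in in_states):  # rule 2
            candidates.add(s)
    return candidates


# ---------------------------------------------------------------------------
# Reconstruction result and karyotype assembly


@dataclass
class ReconstructionResult:
    taxon: str
    variants: list[Karyotype]
    #: (unit, tuple of tied placement states) -- one entry per ambiguity
    alternatives: list[tuple[tuple[str, ...], tuple[object, ...]]]
    per_character_changes: dict[tuple[str, ...], int]
    unplaced: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def ancestral_minichromosomes(self) -> tuple[Minichromosome, ...]:
        return self.variants[0].minichromosomes


def _order_units(
    units: list[tuple[str, ...]],
    states: dict[tuple[str, ...], tuple],
    witnesses: list[Karyotype],
) -> list[tuple[str, ...]]:
    """Order the units sharing one ancestral slot.

    The within-slot order is taken from any taxon that exhibits the winning
    placement for *all* of the slot's units (ordered by position there);
    falls back to sorted unit names if no single witness covers the slot.
    """
    from .characters import unit_state  # local import to avoid a cycle

    if len(units) <= 1:
        return list(units)
    for k in witnesses:
        if all(unit_state(k, u) == states[u] for u in units):
            return sorted(units, key=lambda u: k.find(u[0]))
    return sorted(units)


def _assemble(
    backbones: list[BackboneKey],
    trna_placements: dict[tuple[str, ...], tuple],
    witnesses: list[Karyotype],
    taxon: str,
    genus: str,
) -> tuple[Karyotype, list[tuple[str, ...]]]:
    """Build minichromosomes from backbone skeletons plus slot-level tRNA
    placements; returns the karyotype and any unit whose host/slot did not
    resolve to an existing backbone."""
    by_slot: dict[tuple[BackboneKey, tuple[str, str]], list] = {}
    unplaced: list[tuple[str, ...]] = []
    backbone_set = set(backbones)
    for unit, (host, slot, _rev) in trna_placements.items():
        if host in backbone_set:
            by_slot.setdefault((host, slot), []).append(unit)
        else:
            unplaced.append(unit)
    minis = []
    for key in backbones:
        arrangement: list[OrientedGene] = []
        elements = [NCR] + [name for name, _ in key] + [NCR]
        orient = dict(key)
        for left, right in zip(elements, elements[1:]):
            for unit in _order_units(
                by_slot.get((key, (left, right)), []), trna_placements, witnesses
            ):
                rev = trna_placements[unit][2]
                arrangement.extend(OrientedGene(GeneSymbol(g), rev) for g in unit)
            if right != NCR:
                arrangement.append(OrientedGene(GeneSymbol(right), orient[right]))
        minis.append(Minichromosome(tuple(arrangement)).canonical())
    return (
        Karyotype(taxon=taxon, genus=genus, minichromosomes=tuple(minis)),
        sorted(unplaced),
    )


def infer_ancestor(
    tree: PhylogenyTree,
    karyotypes: dict[str, Karyotype],
    ingroup: set[str],
    outgroup_reference: Karyotype | None = None,
    cluster_mode: bool = True,
    taxon: str = "inferred MRCA",
) -> ReconstructionResult:
    """Reconstruct the ingroup MRCA's karyotype.

    ``karyotypes`` maps tree leaf labels to karyotypes (leaves may be
    omitted: they are all-NA).  ``outgroup_reference`` is an additional
    karyotype that votes as outgroup-side evidence in rule 1 without being a
    tree leaf (its changes are not counted).
    """
    if not tree.ingroup_is_monophyletic(set(ingroup)):
        raise ValueError("ingroup must be a monophyletic set of leaves")
    all_taxa: dict[str, Karyotype | None] = {
        label: karyotypes.get(label) for label in tree.leaf_labels()
    }
    ref_label = None
    if outgroup_reference is not None:
        ref_label = outgroup_reference.taxon or "__reference__"
        all_taxa[ref_label] = outgroup_reference

    backbone_chars, trna_chars = extract_characters(all_taxa, cluster_mode)

    def ref_states(char: CharacterState) -> tuple:
        if ref_label is None:
            return ()
        return (char.state_of(ref_label),)

    def tree_char(char: CharacterState) -> CharacterState:
        if ref_label is None:
            return char
        states = tuple((t, s) for t, s in char.states if t != ref_label)
        return CharacterState(char.kind, char.unit, states)

    per_changes: dict[tuple[str, ...], int] = {}
    alternatives: list[tuple[tuple[str, ...], tuple[object, ...]]] = []
    unplaced: list[tuple[str, ...]] = []

    def resolve(char: CharacterState) -> tuple[object, ...]:
        """Winning state(s) for one character (several iff tied)."""
        tchar = tree_char(char)
        in_states = {
            s for t, s in tchar.states if t in ingroup and s != NA
        }
        if not in_states:
            return ()
        cands = candidate_states(tchar, set(ingroup), ref_states(char))
        rule_backed = bool(cands)
        if not rule_backed:
            cands = in_states  # least-changes fallback (see module docstring)
        scored = {
            c: parsimony_changes(tree, tchar, c, set(ingroup)) for c in cands
        }
        best = min(scored.values())
        winners = tuple(sorted((c for c, v in scored.items() if v == best), key=repr))
        per_changes[char.unit] = best
        return winners

    # --- backbones first -------------------------------------------------
    backbone_of: dict[str, BackboneKey] = {}
    for char in backbone_chars:
        winners = resolve(char)
        if not winners:
            unplaced.append(char.unit)
            continue
        if len(winners) > 1:
            alternatives.append((char.unit, winners))
        backbone_of[char.unit[0]] = winners[0]
    backbone_set: list[BackboneKey] = sorted(set(backbone_of.values()))
    # consistency: every coding gene's chosen key must list exactly the genes
    # that chose it
    for key in backbone_set:
        members = {n for n, _ in key}
        chose = {g for g, k in backbone_of.items() if k == key}
        if members != chose:
            raise KaryotypeError(
                f"inconsistent ancestral backbone resolution for {key}"
            )

    # --- tRNA placements, conditional on the backbone ---------------------
    trna_winner_sets: dict[tuple[str, ...], tuple[object, ...]] = {}
    for char in trna_chars:
        winners = resolve(char)
        winners = tuple(
            w for w in winners if w[0] in set(backbone_set)
        )
        if not winners:
            unplaced.append(char.unit)
            per_changes.pop(char.unit, None)
            continue
        if len(winners) > 1:
            alternatives.append((char.unit, winners))
        trna_winner_sets[char.unit] = winners

    # --- assemble one karyotype per combination of tied placements --------
    ambiguous = [u for u, ws in trna_winner_sets.items() if len(ws) > 1]
    variants: list[Karyotype] = []
    genus = next(iter(karyotypes.values())).genus if karyotypes else ""
    witnesses = [k for k in all_taxa.values() if k is not None]
    for combo in itertools.product(*[trna_winner_sets[u] for u in ambiguous]):
        chosen = {u: trna_winner_sets[u][0] for u in trna_winner_sets}
        chosen.update(dict(zip(ambiguous, combo)))
        kyt, leftover = _assemble(backbone_set, chosen, witnesses, taxon, genus)
        variants.append(kyt)
        for u in leftover:
            if u not in unplaced:
                unplaced.append(u)
    return ReconstructionResult(
        taxon=taxon,
        variants=variants,
        alternatives=sorted(alternatives),
        per_character_changes=per_changes,
        unplaced=sorted(unplaced),
    )
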