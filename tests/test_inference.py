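"""Two-rule parsimony ancestral inference and Sankoff change counting."""

import itertools

import pytest

from lousemito.characters import NA, CharacterState, detect_clusters, extract_characters
from lousemito.fixtures import POLYPLAX_TAXA, polyplax_karyotypes
from lousemito.karyotype import parse_karyotype
from lousemito.parsimony import (
    PhylogenyTree,
    candidate_states,
    infer_ancestor,
    parsimony_changes,
    sankoff_changes,
)


def brute_force_changes(node, tip_states, root_state, alphabet):
    """Exhaustive minimum over all internal-node labelings (oracle)."""
    internals = [
        n for n in node.preorder_iter() if not n.is_leaf() and n is not node
    ]
    best = None
    for combo in itertools.product(alphabet, repeat=len(internals)):
        assign = dict(zip((id(n) for n in internals), combo))
        assign[id(node)] = root_state

        def state_of(n):
            if n.is_leaf():
                return tip_states.get(n.taxon.label, NA)
            return assign[id(n)]

        cost = 0
        for n in node.preorder_iter():
            for child in n.child_nodes():
                s = state_of(child)
                if s == NA:
                    continue
                if s != state_of(n):
                    cost += 1
        if best is None or cost < best:
            best = cost
    return best


class TestSankoff:
    def test_all_tips_identical_means_zero_changes(self):
        tree = PhylogenyTree.from_newick("((a,b),(c,d));")
        tips = {t: "x" for t in "abcd"}
        assert sankoff_changes(tree.tree.seed_node, tips, "x", ["x", "y"]) == 0

    def test_matches_brute_force_on_four_leaves_exhaustively(self):
        tree = PhylogenyTree.from_newick("((a,b),(c,d));")
        node = tree.tree.seed_node
        alphabet = [0, 1]
        for combo in itertools.product(alphabet, repeat=4):
            tips = dict(zip("abcd", combo))
            for root_state in alphabet:
                assert sankoff_changes(node, tips, root_state, alphabet) == (
                    brute_force_changes(node, tips, root_state, alphabet)
                )

    def test_matches_brute_force_on_six_leaves_three_states(self):
        tree = PhylogenyTree.from_newick("(((a,b),c),((d,e),f));")
        node = tree.tree.seed_node
        alphabet = [0, 1, 2]
        leaves = list("abcdef")
        # deterministic sample of tip-state combinations, including NA tips
        combos = list(itertools.product([0, 1, 2, NA], repeat=3))
        for head in combos:
            tail = (head[::-1] + (0, 1, 2))[:3]
            tips = {
                t: s
                for t, s in zip(leaves, head + tail)
                if s != NA
            }
            for root_state in alphabet:
                assert sankoff_changes(node, tips, root_state, alphabet) == (
                    brute_force_changes(node, tips, root_state, alphabet)
                )


class TestCandidateRules:
    def _char(self, states):
        return CharacterState("trna", ("X",), tuple(states.items()))

    def test_rule1_shared_with_outside_taxon(self):
        char = self._char({"i1": "p", "i2": "q", "o1": "p"})
        assert candidate_states(char, {"i1", "i2"}) == {"p"}

    def test_rule2_shared_by_whole_ingroup(self):
        char = self._char({"i1": "p", "i2": "p", "o1": "r"})
        assert "p" in candidate_states(char, {"i1", "i2"})

    def test_private_minority_placement_is_no_candidate(self):
        char = self._char({"i1": "p", "i2": "q", "i3": "q", "o1": "r"})
        assert candidate_states(char, {"i1", "i2", "i3"}) == set()

    def test_reference_votes_in_rule1_only(self):
        char = self._char({"i1": "p", "i2": "q"})
        assert candidate_states(char, {"i1", "i2"}, ("p",)) == {"p"}

    def test_na_taxa_do_not_vote(self):
        char = self._char({"i1": "p", "i2": NA, "o1": "p"})
        assert candidate_states(char, {"i1", "i2"}) == {"p"}

    def test_all_na_character_is_an_error(self):
        char = self._char({"i1": NA, "o1": NA})
        with pytest.raises(ValueError, match="uninformative"):
            candidate_states(char, {"i1"})


class TestClusters:
    def test_s1_s2_detected_as_the_only_multi_taxon_cluster(self, karyos, anoplura_mrca):
        taxa = dict(karyos)
        taxa["Anoplura_MRCA"] = anoplura_mrca
        clusters = detect_clusters(taxa)
        assert ("S1", "S2") in clusters
        # T-D is adjacent in two species only; never a cluster
        assert all("T" not in c for c in clusters)

    def test_characters_emit_na_for_missing_genes(self):
        a = parse_karyotype("#taxon=a\ncox1-A\nrrnS\n")
        b = parse_karyotype("#taxon=b\ncox1\nrrnS-A\n")
        c = parse_karyotype("#taxon=c\ncox1\nrrnS\n")  # A missing
        _, trna = extract_characters({"a": a, "b": b, "c": c})
        (char,) = [ch for ch in trna if ch.unit == ("A",)]
        assert char.state_of("c") == NA
        assert char.state_of("a") != char.state_of("b")


class TestInference:
    def test_polyplax_mrca_matches_published_reconstruction(
        self, tree, karyos, anoplura_mrca, ingroup, mrca_variants
    ):
        res = infer_ancestor(
            tree, karyos, ingroup, outgroup_reference=anoplura_mrca
        )
        assert len(res.variants) == 2
        assert all(len(v.minichromosomes) == 11 for v in res.variants)
        assert [u for u, _ in res.alternatives] == [("S1", "S2")]
        inferred = {
            frozenset(tuple(mc.genes) for mc in v.minichromosomes)
            for v in res.variants
        }
        bundled = {
            frozenset(tuple(mc.genes) for mc in v.minichromosomes)
            for v in mrca_variants
        }
        assert inferred == bundled
        assert res.unplaced == []

    def test_every_variant_is_a_valid_complete_karyotype(
        self, tree, karyos, anoplura_mrca, ingroup
    ):
        res = infer_ancestor(
            tree, karyos, ingroup, outgroup_reference=anoplura_mrca
        )
        for v in res.variants:
            assert v.complete  # each of the 37 genes placed exactly once

    def test_identical_tips_reconstruct_identically_with_zero_changes(self, tree, reclinata):
        from dataclasses import replace

        karyos = {
            t: replace(reclinata, taxon=t)
            for t in POLYPLAX_TAXA
        }
        res = infer_ancestor(tree, karyos, set(POLYPLAX_TAXA))
        assert len(res.variants) == 1
        assert res.alternatives == []
        assert set(res.per_character_changes.values()) == {0}
        assert {tuple(mc.genes) for mc in res.variants[0].minichromosomes} == {
            tuple(mc.genes) for mc in reclinata.minichromosomes
        }

    def test_reduced_ingroup_adopts_shared_derived_arrangement(
        self, tree, karyos, anoplura_mrca
    ):
        # without P. asiatica, the reclinata+spinulosa arrangement
        # T-D-Y-cox2-nad6-A is ancestral for the reduced ingroup by rule 2
        reduced = {
            t: k for t, k in karyos.items() if t != "Polyplax_asiatica"
        }
        res = infer_ancestor(
            tree,
            reduced,
            {"Polyplax_reclinata", "Polyplax_spinulosa"},
            outgroup_reference=anoplura_mrca,
        )
        strings = {str(mc) for v in res.variants for mc in v.minichromosomes}
        assert "~T-D-Y-cox2-nad6-A" in strings

    def test_invariant_to_taxon_input_order(self, tree, karyos, anoplura_mrca, ingroup):
        res_fwd = infer_ancestor(
            tree, dict(karyos), ingroup, outgroup_reference=anoplura_mrca
        )
        res_rev = infer_ancestor(
            tree,
            dict(reversed(list(karyos.items()))),
            ingroup,
            outgroup_reference=anoplura_mrca,
        )
        key = lambda res: {
            frozenset(tuple(mc.genes) for mc in v.minichromosomes)
            for v in res.variants
        }
        assert key(res_fwd) == key(res_rev)

    def test_invariant_to_outgroup_clade_resolution(
        self, karyos, anoplura_mrca, ingroup, mrca_variants
    ):
        # alternative arrangement of the Pediculus/Pthirus/Pedicinus/
        # Haematopinus clade (published data constrain it only partially)
        alt = PhylogenyTree.from_newick(
            "(Haematomyzus_elephantis,(Microthoracius_praelongiceps,"
            "(((Polyplax_asiatica,(Polyplax_spinulosa,Polyplax_reclinata)),"
            "(Hoplopleura_akanezumi,Hoplopleura_kitti)),"
            "((Haematopinus_asini,(Haematopinus_apri,Haematopinus_suis)),"
            "((Pedicinus_obtusus,Pedicinus_badii),"
            "(Pthirus_pubis,(Pediculus_schaeffi,(Pediculus_capitis,"
            "Pediculus_humanus))))))));"
        )
        res = infer_ancestor(
            alt, karyos, ingroup, outgroup_reference=anoplura_mrca
        )
        inferred = {
            frozenset(tuple(mc.genes) for mc in v.minichromosomes)
            for v in res.variants
        }
        bundled = {
            frozenset(tuple(mc.genes) for mc in v.minichromosomes)
            for v in mrca_variants
        }
        assert inferred == bundled

    def test_universal_shared_placement_costs_zero_changes(
        self, tree, karyos, anoplura_mrca, ingroup
    ):
        res = infer_ancestor(
            tree, karyos, ingroup, outgroup_reference=anoplura_mrca
        )
        # genes that never moved inside Polyplax and match the outgroup side
        for unit in [("E",), ("I",), ("R",), ("V",), ("W",), ("C",)]:
            assert res.per_character_changes[unit] == 0

    def test_s1_s2_candidates_tie_on_change_count(
        self, tree, karyos, anoplura_mrca, ingroup
    ):
        all_taxa = {t: karyos.get(t) for t in tree.leaf_labels()}
        all_taxa["Anoplura_MRCA"] = anoplura_mrca
        _, trna = extract_characters(all_taxa)
        (char,) = [c for c in trna if c.unit == ("S1", "S2")]
        states = tuple((t, s) for t, s in char.states if t != "Anoplura_MRCA")
        char_on_tree = CharacterState(char.kind, char.unit, states)
        upstream_rrns = char.state_of("Polyplax_reclinata")
        downstream_nad1 = char.state_of("Polyplax_asiatica")
        c1 = parsimony_changes(tree, char_on_tree, upstream_rrns, ingroup)
        c2 = parsimony_changes(tree, char_on_tree, downstream_nad1, ingroup)
        assert c1 == c2 == 1
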