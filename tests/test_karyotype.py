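"""Karyotype model, .kyt format, slot enumeration, backbone projection."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lousemito.genes import ALL_GENES, TRNA_GENES, GeneSymbol, gene_category
from lousemito.karyotype import (
    Karyotype,
    KaryotypeError,
    Minichromosome,
    OrientedGene,
    enumerate_slots,
    parse_karyotype,
    project_backbone,
    shared_minichromosomes,
    write_karyotype,
)


class TestGenes:
    def test_gene_set_has_37_members(self):
        assert len(ALL_GENES) == 37
        assert len(TRNA_GENES) == 22

    def test_category_and_anticodon(self):
        assert gene_category("nad4L") == "PCG"
        assert gene_category("rrnS") == "rRNA"
        assert GeneSymbol("L1").anticodon_tag == "tag"
        assert GeneSymbol("S2").anticodon_tag == "tga"
        assert GeneSymbol("cox1").anticodon_tag is None

    def test_unknown_token_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            GeneSymbol("nad7")


class TestParsing:
    def test_reclinata_fixture(self, reclinata):
        assert len(reclinata.minichromosomes) == 11
        assert reclinata.n_genes() == 37
        assert reclinata.complete
        reversed_genes = {
            g.name
            for mc in reclinata.minichromosomes
            for g in mc.genes
            if g.reversed
        }
        assert reversed_genes == {"nad1", "T"}

    def test_round_trip(self, karyos, mrca_variants, anoplura_mrca):
        for k in [*karyos.values(), *mrca_variants, anoplura_mrca]:
            again = parse_karyotype(write_karyotype(k))
            assert again.sorted_minichromosomes() == k.sorted_minichromosomes()
            assert again.taxon == k.taxon and again.genus == k.genus

    def test_empty_document_rejected(self):
        with pytest.raises(KaryotypeError, match="no minichromosome"):
            parse_karyotype("# only a comment\n")

    def test_duplicate_across_minichromosomes_rejected(self):
        with pytest.raises(KaryotypeError, match="A already placed"):
            parse_karyotype("cox1-A\nrrnS-A\n")

    def test_unknown_token_names_line(self):
        with pytest.raises(KaryotypeError, match="line 2.*'bogus'"):
            parse_karyotype("cox1\nrrnS-bogus\n")

    def test_oversized_minichromosome_rejected(self):
        line = "-".join(["A", "C", "D", "E", "F", "G", "H", "I", "K"])
        with pytest.raises(KaryotypeError, match="9 genes"):
            parse_karyotype(line + "\n")

    def test_majority_strand_canonicalization(self):
        # written on the minority strand: every gene flipped, order reversed
        k = parse_karyotype("~W-~nad3-~G-nad1\n")
        assert str(k.minichromosomes[0]) == "~nad1-G-nad3-W"


class TestSlots:
    @pytest.mark.parametrize(
        "doc, expected",
        [
            ("cox1-A\n", (2, 1, 3)),
            ("cox1\n", (2, 0, 2)),
        ],
    )
    def test_toy_counts(self, doc, expected):
        res = enumerate_slots(parse_karyotype(doc))
        assert (res.adjacent_count, res.intergenic_count, res.total) == expected

    def test_ancestral_polyplax_census_base(self, mrca_variants):
        res = enumerate_slots(mrca_variants[0])
        assert (res.adjacent_count, res.intergenic_count, res.total) == (22, 26, 48)

    def test_closed_form_matches_exhaustive_listing(
        self, karyos, mrca_variants, anoplura_mrca
    ):
        for k in [*karyos.values(), *mrca_variants, anoplura_mrca]:
            res = enumerate_slots(k)
            g, m = k.n_genes(), len(k.minichromosomes)
            assert res.total == len(res.slots) == g + m
            assert res.adjacent_count == 2 * m
            assert res.intergenic_count == g - m
            by_class = [s.slot_class for s in res.slots]
            assert by_class.count("intergenic") == res.intergenic_count


class TestBackbone:
    def test_reclinata_backbone_sizes(self, reclinata):
        proj = project_backbone(reclinata)
        sizes = sorted(len(mc.genes) for mc in proj.minichromosomes)
        assert sizes.count(1) == 7 and sizes.count(2) == 4

    def test_polyplax_backbones_identical(self, karyos):
        sets = {k.backbone_set() for k in karyos.values()}
        assert len(sets) == 1

    def test_idempotent(self, reclinata):
        once = project_backbone(reclinata)
        twice = project_backbone(once)
        assert once.sorted_minichromosomes() == twice.sorted_minichromosomes()

    def test_trna_only_minichromosome_becomes_flagged_placeholder(self):
        k = parse_karyotype("cox1\nA-C-D\n")
        proj = project_backbone(k)
        placeholders = [mc for mc in proj.minichromosomes if mc.placeholder]
        assert len(placeholders) == 1 and placeholders[0].genes == ()
        assert len(proj.minichromosomes) == len(k.minichromosomes)


class TestSharedMinichromosomes:
    def test_reclinata_vs_spinulosa(self, reclinata, spinulosa):
        res = shared_minichromosomes(reclinata, spinulosa)
        assert res.n_shared == 9
        assert res.differing_genes == {"L1", "L2"}

    def test_reclinata_vs_asiatica(self, reclinata, asiatica):
        res = shared_minichromosomes(reclinata, asiatica)
        assert res.n_shared == 4
        assert res.differing_genes == {"A", "F", "P", "S1", "S2", "T"}

    def test_reflexive_and_symmetric(self, karyos):
        for a in karyos.values():
            same = shared_minichromosomes(a, a)
            assert same.n_shared == len(a.minichromosomes)
            assert same.differing_genes == frozenset()
            for b in karyos.values():
                ab = shared_minichromosomes(a, b)
                ba = shared_minichromosomes(b, a)
                assert ab.n_shared == ba.n_shared
                assert ab.differing_genes == ba.differing_genes

    def test_orientation_difference_is_a_non_match(self):
        a = parse_karyotype("cox1-T\n")
        b = parse_karyotype("cox1-~T\n")
        res = shared_minichromosomes(a, b)
        assert res.n_shared == 0
        assert res.differing_genes == {"T"}


@st.composite
def random_karyotypes(draw):
    genes = draw(st.permutations(sorted(ALL_GENES)))
    n = draw(st.integers(min_value=6, max_value=37))
    genes = genes[:n]
    minis, i = [], 0
    while i < len(genes):
        size = draw(st.integers(min_value=1, max_value=min(8, len(genes) - i)))
        minis.append(
            Minichromosome(
                tuple(OrientedGene(GeneSymbol(g)) for g in genes[i : i + size])
            )
        )
        i += size
    return Karyotype(taxon="random", genus="none", minichromosomes=tuple(minis))


class TestProperties:
    @settings(max_examples=50, derandomize=True)
    @given(random_karyotypes())
    def test_slot_closed_form(self, k):
        res = enumerate_slots(k)
        assert res.adjacent_count + res.intergenic_count == res.total
        assert res.total == k.n_genes() + len(k.minichromosomes)

    @settings(max_examples=50, derandomize=True)
    @given(random_karyotypes())
    def test_format_round_trip(self, k):
        again = parse_karyotype(write_karyotype(k))
        assert again.sorted_minichromosomes() == k.sorted_minichromosomes()

    @settings(max_examples=25, derandomize=True)
    @given(random_karyotypes())
    def test_backbone_projection_idempotent(self, k):
        once = project_backbone(k)
        assert project_backbone(once).sorted_minichromosomes() == (
            once.sorted_minichromosomes()
        )
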