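"""Bundled data: louse karyotypes, the sucking-louse phylogeny, and the
table of non-*Polyplax* translocation arrangement pairs."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .events import ArrangementPair
from .karyotype import Karyotype, parse_karyotype
from .parsimony import PhylogenyTree

#: Census base (NCR-adjacent, intergenic, total slots) used with the
#: sucking-louse MRCA karyotype: the published census counts 35 placed genes
#: on 11 minichromosomes (two genes unplaced), i.e. 22 + 24 = 46 slots, even
#: though the arrangement strings account for more genes.
SUCKING_LICE_MRCA_CENSUS_BASE = (22, 24, 46)

POLYPLAX_TAXA = (
    "Polyplax_reclinata",
    "Polyplax_spinulosa",
    "Polyplax_asiatica",
)

_KYT_FILES = {
    "Polyplax_reclinata": "polyplax_reclinata.kyt",
    "Polyplax_spinulosa": "polyplax_spinulosa.kyt",
    "Polyplax_asiatica": "polyplax_asiatica.kyt",
    "Polyplax_MRCA_S1S2_rrnS": "polyplax_mrca_rrns_variant.kyt",
    "Polyplax_MRCA_S1S2_nad1": "polyplax_mrca_nad1_variant.kyt",
    "Anoplura_MRCA": "sucking_lice_mrca.kyt",
}


def _read(name: str) -> str:
    return (resources.files("lousemito.data") / name).read_text()


def load_karyotype(taxon: str) -> Karyotype:
    """Load a bundled karyotype by taxon label."""
    try:
        fname = _KYT_FILES[taxon]
    except KeyError:
        raise KeyError(
            f"no bundled karyotype for {taxon!r}; available: {sorted(_KYT_FILES)}"
        ) from None
    return parse_karyotype(_read(fname))


def polyplax_karyotypes() -> dict[str, Karyotype]:
    return {t: load_karyotype(t) for t in POLYPLAX_TAXA}


def polyplax_mrca_variants() -> tuple[Karyotype, Karyotype]:
    """The two equally parsimonious ancestral Polyplax karyotypes
    (S1-S2 upstream of rrnS; S1-S2 downstream of nad1)."""
    return (
        load_karyotype("Polyplax_MRCA_S1S2_rrnS"),
        load_karyotype("Polyplax_MRCA_S1S2_nad1"),
    )


def sucking_lice_mrca() -> Karyotype:
    return load_karyotype("Anoplura_MRCA")


def sucking_lice_tree() -> PhylogenyTree:
    """The 16-leaf rooted phylogeny (15 sucking lice + elephant louse)."""
    return PhylogenyTree.from_newick(_read("sucking_lice.nwk"))


def nonpolyplax_pair_table() -> list[ArrangementPair]:
    """Arrangement pairs for the 12 non-Polyplax species vs the
    sucking-louse MRCA (one row per species per derived arrangement)."""
    with resources.as_file(
        resources.files("lousemito.data") / "nonpolyplax_translocations.tsv"
    ) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        ArrangementPair(
            gene=r.gene,
            mrca_arrangement=r.mrca_arrangement,
            derived_arrangement=r.derived_arrangement,
            species=r.species,
            genus=r.genus,
        )
        for r in df.itertuples()
    ]
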