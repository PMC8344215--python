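"""The canonical 37-gene animal mitochondrial gene set.

Gene tokens follow the naming used for fragmented louse mitogenomes:
protein-coding genes and rRNAs keep their lowercase abbreviations
(``atp6`` ... ``rrnL``), tRNA genes are single-letter amino-acid codes,
with the leucine and serine isoacceptors distinguished as ``L1``/``L2``
and ``S1``/``S2`` by their anticodons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

PCG_GENES = frozenset(
    {
        "atp6",
        "atp8",
        "cox1",
        "cox2",
        "cox3",
        "cob",
        "nad1",
        "nad2",
        "nad3",
        "nad4",
        "nad4L",
        "nad5",
        "nad6",
    }
)

RRNA_GENES = frozenset({"rrnS", "rrnL"})

TRNA_GENES = frozenset(
    {
        "A",
        "C",
        "D",
        "E",
        "F",
        "G",
        "H",
        "I",
        "K",
        "L1",
        "L2",
        "M",
        "N",
        "P",
        "Q",
        "R",
        "S1",
        "S2",
        "T",
        "V",
        "W",
        "Y",
    }
)

ALL_GENES = PCG_GENES | RRNA_GENES | TRNA_GENES

#: Anticodons that tell apart the duplicated leucine/serine tRNAs.
ANTICODON_TAGS = {"L1": "tag", "L2": "taa", "S1": "tct", "S2": "tga"}

#: tRNA pairs that can exchange identity through an anticodon change
#: (point mutation at the third anticodon position) rather than by
#: physically moving.
IDENTITY_SWAP_PAIRS = (frozenset({"L1", "L2"}), frozenset({"S1", "S2"}))

NCR = "NCR"  # sentinel for the non-coding / control region


def gene_category(name: str) -> str:
    """Return ``"PCG"``, ``"rRNA"`` or ``"tRNA"`` for a gene token."""
    if name in PCG_GENES:
        return "PCG"
    if name in RRNA_GENES:
        return "rRNA"
    if name in TRNA_GENES:
        return "tRNA"
    raise ValueError(f"unknown mitochondrial gene token: {name!r}")


@dataclass(frozen=True)
class GeneSymbol:
    """One of the 37 admissible mitochondrial gene tokens."""

    name: str
    category: str = field(init=False)
    anticodon_tag: str | None = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", gene_category(self.name))
        object.__setattr__(self, "anticodon_tag", ANTICODON_TAGS.get(self.name))

    @property
    def is_trna(self) -> bool:
        return self.category == "tRNA"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name
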