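"""Data model and plain-text format for fragmented mitochondrial karyotypes.

A *karyotype* is a species' full mitochondrial genome organised as a set of
circular minichromosomes.  Each minichromosome carries a short ordered run of
genes plus a single non-coding region (NCR, the control region) that closes
the circle.  A minichromosome is written as its canonical linearization: the
gene immediately downstream of the NCR comes first, the NCR is implicit at
both ends.  A ``~`` prefix marks a gene transcribed opposite to the majority
orientation (in the bundled louse data this is ``nad1``, plus the inverted
``trnT`` of *Polyplax reclinata* and *P. spinulosa*).

File format (``.kyt``, UTF-8)::

    #taxon=Polyplax reclinata
    #genus=Polyplax
    atp8-atp6
    ~T-D-Y-cox2-nad6-A
    ...

``#`` starts a comment; ``#taxon=`` / ``#genus=`` headers name the species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .genes import ALL_GENES, NCR, TRNA_GENES, GeneSymbol

MAX_GENES_PER_MINICHROMOSOME = 8


class KaryotypeError(ValueError):
    """Validation failure in a karyotype or a karyotype document."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class OrientedGene:
    """A gene plus its transcription orientation relative to the NCR."""

    gene: GeneSymbol
    reversed: bool = False

    @classmethod
    def from_token(cls, token: str) -> "OrientedGene":
        rev = token.startswith("~")
        return cls(GeneSymbol(token[1:] if rev else token), rev)

    @property
    def name(self) -> str:
        return self.gene.name

    def flipped(self) -> "OrientedGene":
        return OrientedGene(self.gene, not self.reversed)

    def token(self) -> str:
        return ("~" if self.reversed else "") + self.gene.name


#: A minichromosome's identity with tRNAs stripped: the ordered, oriented
#: protein-coding/rRNA genes.  This is the stable unit of comparison between
#: species ("backbone").
BackboneKey = tuple[tuple[str, bool], ...]


@dataclass(frozen=True)
class Minichromosome:
    """One circular minichromosome, canonically linearized (NCR implicit)."""

    genes: tuple[OrientedGene, ...]
    #: set by :func:`project_backbone` for minichromosomes whose coding
    #: region was tRNA-only and is therefore empty after projection.
    placeholder: bool = False

    def __post_init__(self) -> None:
        if not self.placeholder and not (
            1 <= len(self.genes) <= MAX_GENES_PER_MINICHROMOSOME
        ):
            raise KaryotypeError(
                f"a minichromosome must carry 1-{MAX_GENES_PER_MINICHROMOSOME} "
                f"genes, got {len(self.genes)}"
            )
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise KaryotypeError(f"duplicate gene within a minichromosome: {names}")

    @classmethod
    def from_string(cls, text: str) -> "Minichromosome":
        tokens = [t for t in text.strip().split("-") if t]
        return cls(tuple(OrientedGene.from_token(t) for t in tokens)).canonical()

    def canonical(self) -> "Minichromosome":
        """Flip the whole circle if most genes are marked reversed.

        The linearization is anchored at the NCR, so the only remaining
        freedom is which strand is written; the majority strand is chosen.
        """
        n_rev = sum(g.reversed for g in self.genes)
        if 2 * n_rev > len(self.genes):
            return Minichromosome(
                tuple(g.flipped() for g in reversed(self.genes)), self.placeholder
            )
        return self

    def gene_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genes)

    def backbone(self) -> BackboneKey:
        return tuple(
            (g.name, g.reversed) for g in self.genes if not g.gene.is_trna
        )

    def trna_count(self) -> int:
        return sum(g.gene.is_trna for g in self.genes)

    def __str__(self) -> str:
        return "-".join(g.token() for g in self.genes) if self.genes else "(NCR only)"


@dataclass(frozen=True)
class Karyotype:
    """A species' mitochondrial genome as a set of minichromosomes."""

    taxon: str
    genus: str
    minichromosomes: tuple[Minichromosome, ...]

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for i, mc in enumerate(self.minichromosomes):
            for g in mc.genes:
                if g.name in seen:
                    raise KaryotypeError(
                        f"gene {g.name} appears on two minichromosomes "
                        f"(#{seen[g.name] + 1} and #{i + 1})"
                    )
                seen[g.name] = i

    @property
    def complete(self) -> bool:
        """True when all 37 genes are present exactly once."""
        return self.gene_set() == ALL_GENES

    def gene_set(self) -> frozenset[str]:
        return frozenset(
            g.name for mc in self.minichromosomes for g in mc.genes
        )

    def n_genes(self) -> int:
        return sum(len(mc.genes) for mc in self.minichromosomes)

    def backbone_set(self) -> tuple[BackboneKey, ...]:
        return tuple(sorted(mc.backbone() for mc in self.minichromosomes))

    def sorted_minichromosomes(self) -> tuple[Minichromosome, ...]:
        return tuple(
            sorted(self.minichromosomes, key=lambda mc: (mc.backbone(), str(mc)))
        )

    def find(self, gene: str) -> tuple[int, int]:
        """Return (minichromosome index, position) of a gene."""
        for i, mc in enumerate(self.minichromosomes):
            for j, g in enumerate(mc.genes):
                if g.name == gene:
                    return i, j
        raise KeyError(gene)

    def __str__(self) -> str:
        return f"{self.taxon}: " + "; ".join(
            str(mc) for mc in self.sorted_minichromosomes()
        )


# ---------------------------------------------------------------------------
# .kyt parsing and writing


def parse_karyotype(text: str) -> Karyotype:
    """Parse a ``.kyt`` document into a validated :class:`Karyotype`."""
    taxon = genus = ""
    minis: list[Minichromosome] = []
    placed: dict[str, int] = {}
    saw_content = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("taxon="):
                taxon = body[len("taxon="):].strip()
            elif body.startswith("genus="):
                genus = body[len("genus="):].strip()
            continue
        saw_content = True
        tokens = [t for t in line.split("-") if t]
        genes = []
        for tok in tokens:
            name = tok[1:] if tok.startswith("~") else tok
            if name not in ALL_GENES:
                raise KaryotypeError(f"unknown gene token {tok!r}", lineno)
            if name in placed:
                raise KaryotypeError(
                    f"gene {name} already placed on line {placed[name]}", lineno
                )
            placed[name] = lineno
            genes.append(OrientedGene.from_token(tok))
        if len(genes) > MAX_GENES_PER_MINICHROMOSOME:
            raise KaryotypeError(
                f"minichromosome has {len(genes)} genes "
                f"(max {MAX_GENES_PER_MINICHROMOSOME})",
                lineno,
            )
        if not genes:
            raise KaryotypeError("empty minichromosome line", lineno)
        minis.append(Minichromosome(tuple(genes)).canonical())
    if not saw_content:
        raise KaryotypeError("document contains no minichromosome lines")
    return Karyotype(taxon=taxon, genus=genus, minichromosomes=tuple(minis))


def write_karyotype(k: Karyotype) -> str:
    """Serialize to the ``.kyt`` format (canonical order: sorted by backbone)."""
    lines = [f"#taxon={k.taxon}", f"#genus={k.genus}"]
    lines += [str(mc) for mc in k.sorted_minichromosomes() if mc.genes]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Slot enumeration (the insertion-site census primitive)


@dataclass(frozen=True)
class Slot:
    """An insertion position between two adjacent elements of the circle."""

    minichromosome: int  # index into Karyotype.minichromosomes
    position: int  # insert before genes[position]; len(genes) = before NCR
    slot_class: str  # adjacent_5p | adjacent_3p | intergenic


@dataclass(frozen=True)
class SlotEnumeration:
    adjacent_count: int
    intergenic_count: int
    total: int
    slots: tuple[Slot, ...]


def enumerate_slots(k: Karyotype) -> SlotEnumeration:
    """List every insertion slot, by class.

    A minichromosome with ``g`` genes has ``g + 1`` slots: one at each NCR
    boundary and ``g - 1`` between genes; genome-wide the closed form is
    ``adjacent = 2M``, ``intergenic = G - M``, ``total = G + M``.
    """
    slots: list[Slot] = []
    for i, mc in enumerate(k.minichromosomes):
        g = len(mc.genes)
        for pos in range(g + 1):
            if pos == 0:
                cls = "adjacent_5p"
            elif pos == g:
                cls = "adjacent_3p"
            else:
                cls = "intergenic"
            slots.append(Slot(i, pos, cls))
    adjacent = sum(s.slot_class != "intergenic" for s in slots)
    intergenic = len(slots) - adjacent
    return SlotEnumeration(adjacent, intergenic, len(slots), tuple(slots))


# ---------------------------------------------------------------------------
# Backbone projection and pairwise comparison


def project_backbone(k: Karyotype) -> Karyotype:
    """Strip tRNAs, keeping one (possibly placeholder) entry per circle."""
    minis = []
    for mc in k.minichromosomes:
        coding = tuple(g for g in mc.genes if not g.gene.is_trna)
        minis.append(Minichromosome(coding, placeholder=not coding))
    return replace(k, minichromosomes=tuple(minis))


@dataclass(frozen=True)
class SharedResult:
    shared: tuple[tuple[int, int], ...]  # (index in a, index in b) pairs
    differing_genes: frozenset[str]

    @property
    def n_shared(self) -> int:
        return len(self.shared)


def shared_minichromosomes(a: Karyotype, b: Karyotype) -> SharedResult:
    """Match minichromosomes with identical gene content, order and orientation.

    ``differing_genes`` are the genes whose placement (host minichromosome,
    neighbours or orientation) actually differs between the two karyotypes --
    i.e. the minimal set of moved genes, not every occupant of an unmatched
    minichromosome.
    """
    from .placements import moved_genes  # local import to avoid a cycle

    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for i, mc in enumerate(a.minichromosomes):
        key = tuple(mc.genes)
        for j, other in enumerate(b.minichromosomes):
            if j not in used_b and tuple(other.genes) == key:
                pairs.append((i, j))
                used_b.add(j)
                break
    return SharedResult(tuple(pairs), frozenset(moved_genes(a, b)))
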