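"""Character extraction for ancestral karyotype inference.

Two character families are scored per taxon, mirroring the practice of
treating the stable protein-coding/rRNA backbone separately from the mobile
tRNAs:

* **backbone characters** -- one per protein-coding/rRNA gene; the state is
  the backbone key (ordered, oriented coding genes) of the minichromosome
  hosting it.
* **tRNA placement characters** -- one per tRNA unit; the state is the
  slot-level placement descriptor (host backbone, flanking backbone
  elements, orientation).  In cluster mode, tRNAs that sit next to each
  other in the same order in *every* taxon with data are treated as one
  unit moving as a block (e.g. the S1-S2 cluster).

A taxon missing a unit's gene(s) scores ``NA`` and does not vote anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genes import NCR, TRNA_GENES
from .karyotype import Karyotype
from .placements import Placement, placements

NA = "NA"


@dataclass(frozen=True)
class CharacterState:
    """One character: a unit plus its per-taxon states."""

    kind: str  # "backbone" | "trna"
    unit: tuple[str, ...]  # gene name(s); a single backbone gene or a tRNA unit
    states: tuple[tuple[str, object], ...]  # (taxon, state or NA)

    def state_of(self, taxon: str):
        return dict(self.states)[taxon]

    def taxa_with_data(self) -> list[str]:
        return [t for t, s in self.states if s != NA]

    @property
    def informative(self) -> bool:
        return any(s != NA for _, s in self.states)


def detect_clusters(karyotypes: dict[str, Karyotype]) -> list[tuple[str, ...]]:
    """Find tRNA blocks that are contiguous, in the same order and relative
    orientation, in every karyotype where all member genes are present."""
    taxa = [k for k in karyotypes.values() if k is not None]
    if not taxa:
        return []
    # adjacency graph over ordered tRNA pairs
    def adjacent_pairs(k: Karyotype) -> set[tuple[str, str]]:
        pairs = set()
        for mc in k.minichromosomes:
            genes = mc.genes
            for x, y in zip(genes, genes[1:]):
                if x.gene.is_trna and y.gene.is_trna and x.reversed == y.reversed:
                    pairs.add((x.name, y.name))
        return pairs

    universal: set[tuple[str, str]] = set()
    for k in taxa:
        universal |= adjacent_pairs(k)
    for k in taxa:
        present = k.gene_set()
        pairs = adjacent_pairs(k)
        universal = {
            (a, b)
            for a, b in universal
            if (a, b) in pairs or a not in present or b not in present
        }
    # chain pairs into maximal runs
    nxt = dict(universal)
    has_pred = {b for _, b in universal}
    clusters = []
    for start in sorted(nxt):
        if start in has_pred:
            continue
        run = [start]
        while run[-1] in nxt:
            run.append(nxt[run[-1]])
        if len(run) > 1:
            clusters.append(tuple(run))
    return clusters


def unit_state(k: Karyotype, unit: tuple[str, ...]):
    """Slot-level placement state of a unit in one karyotype (or NA).

    The state is (host backbone, flanking backbone elements, orientation).
    Using the flanking *backbone* elements rather than immediate neighbours
    keeps a gene's state stable when some other tRNA inserts next to it --
    only genes that actually left their slot score a different state.
    """
    present = k.gene_set()
    if any(g not in present for g in unit):
        return NA
    pl = placements(k)
    first = pl[unit[0]]
    if len(unit) > 1:
        # the unit must be contiguous and in order in this taxon
        mci, pos = k.find(unit[0])
        names = k.minichromosomes[mci].gene_names()
        if names[pos : pos + len(unit)] != unit:
            # genes exist but not as the block: score the block as absent here
            return NA
    return (first.host, first.slot, first.reversed)


def extract_characters(
    karyotypes: dict[str, Karyotype | None], cluster_mode: bool = True
) -> tuple[list[CharacterState], list[CharacterState]]:
    """Build the backbone and tRNA character matrices over a taxon set.

    ``karyotypes`` maps taxon label to its karyotype, or ``None`` for taxa
    with no data (they score NA throughout).  Returns
    ``(backbone_characters, trna_characters)``.
    """
    with_data = {t: k for t, k in karyotypes.items() if k is not None}
    if len(with_data) < 2:
        raise ValueError("character extraction needs at least 2 taxa with data")
    taxa = list(karyotypes)

    backbone_chars: list[CharacterState] = []
    coding_genes = sorted(
        {
            g
            for k in with_data.values()
            for g in k.gene_set()
            if g not in TRNA_GENES
        }
    )
    host_of: dict[str, dict[str, object]] = {}
    for t, k in with_data.items():
        host_of[t] = {}
        for mc in k.minichromosomes:
            key = mc.backbone()
            for name, _rev in key:
                host_of[t][name] = key
    for gene in coding_genes:
        states = tuple(
            (t, host_of.get(t, {}).get(gene, NA) if t in with_data else NA)
            for t in taxa
        )
        backbone_chars.append(CharacterState("backbone", (gene,), states))

    units: list[tuple[str, ...]]
    clustered: set[str] = set()
    units = []
    if cluster_mode:
        for cl in detect_clusters(with_data):
            units.append(cl)
            clustered.update(cl)
    trna_genes = sorted(
        {
            g
            for k in with_data.values()
            for g in k.gene_set()
            if g in TRNA_GENES and g not in clustered
        }
    )
    units.extend((g,) for g in trna_genes)

    trna_chars = []
    for unit in sorted(units):
        states = tuple(
            (t, unit_state(with_data[t], unit) if t in with_data else NA)
            for t in taxa
        )
        trna_chars.append(CharacterState("trna", unit, states))
    return backbone_chars, trna_chars
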