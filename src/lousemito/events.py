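"""Detection, classification and grouping of tRNA translocation events.

An event is a tRNA gene (or a block of tRNAs moving together) whose placement
differs between an ancestral and a derived karyotype.  Destinations are
classified relative to the control region (NCR): ``adjacent`` when the unit
flanks the NCR at either end of its minichromosome, ``inside_NCR`` when it
sits within the NCR itself (representable only through annotation, counted
with ``adjacent`` downstream), ``intergenic`` otherwise.

Reciprocal anticodon swaps (e.g. trnL1/trnL2 exchanging identities through a
third-anticodon-position mutation) are flagged ``identity_swap`` and excluded
from translocation statistics, while still counting as position changes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .genes import IDENTITY_SWAP_PAIRS, NCR
from .karyotype import Karyotype
from .placements import Placement, moved_genes, placements

DEST_ADJACENT = "adjacent"
DEST_INSIDE_NCR = "inside_NCR"
DEST_INTERGENIC = "intergenic"


class BackboneMismatchError(ValueError):
    """The two karyotypes differ in backbone content.

    Minichromosome splits/mergers are outside translocation detection; use a
    karyotype-level comparison instead.
    """


@dataclass(frozen=True)
class TranslocationEvent:
    unit: tuple[str, ...]
    source: str  # placement descriptor (ancestor) or arrangement string
    destination: str  # placement descriptor (derived) or arrangement string
    destination_class: str
    inverted: bool
    identity_swap: bool
    species: tuple[str, ...]
    genus: str

    def group_key(self) -> tuple:
        return (self.genus, self.unit, self.destination)


@dataclass(frozen=True)
class EventGroup:
    """Events shared by congeneric species, counted once."""

    genus: str
    unit: tuple[str, ...]
    destination: str
    destination_class: str
    members: tuple[TranslocationEvent, ...]

    @property
    def adjacent(self) -> bool:
        return self.destination_class in (DEST_ADJACENT, DEST_INSIDE_NCR)


def _block_runs(moved: set[str], anc: Karyotype, der: Karyotype) -> list[tuple[str, ...]]:
    """Partition the moved tRNAs into maximal blocks contiguous (same order,
    same relative orientation) in BOTH karyotypes."""

    def pairs(k: Karyotype) -> set[tuple[str, str]]:
        out = set()
        for mc in k.minichromosomes:
            for x, y in zip(mc.genes, mc.genes[1:]):
                if (
                    x.name in moved
                    and y.name in moved
                    and x.reversed == y.reversed
                ):
                    out.add((x.name, y.name))
        return out

    der_pairs = pairs(der)
    # a pair survives in order, or reversed when the whole block inverted
    preserved = der_pairs | {(b, a) for a, b in der_pairs}
    both = pairs(anc) & preserved
    nxt = dict(both)
    has_pred = {b for _, b in both}
    runs = []
    used: set[str] = set()
    for g in sorted(moved):
        if g in has_pred or g in used:
            continue
        run = [g]
        while run[-1] in nxt and nxt[run[-1]] not in used:
            run.append(nxt[run[-1]])
        used.update(run)
        runs.append(tuple(run))
    for g in sorted(moved - used):  # safety net for cyclic leftovers
        runs.append((g,))
    return runs


def _unit_destination_class(der: Karyotype, unit: tuple[str, ...]) -> str:
    mci, _ = der.find(unit[0])
    mc = der.minichromosomes[mci]
    positions = [i for i, g in enumerate(mc.genes) if g.name in unit]
    if min(positions) == 0 or max(positions) == len(mc.genes) - 1:
        return DEST_ADJACENT
    return DEST_INTERGENIC


def detect_events(
    ancestor: Karyotype,
    derived: Karyotype,
    cluster_mode: bool = True,
) -> list[TranslocationEvent]:
    """Events explaining ``derived`` from ``ancestor`` (same backbone set)."""
    if ancestor.backbone_set() != derived.backbone_set():
        raise BackboneMismatchError(
            "backbone change between karyotypes: use karyotype-level comparison"
        )
    moved = {g for g in moved_genes(ancestor, derived)}
    pa, pd = placements(ancestor), placements(derived)
    moved = {g for g in moved if g in pa and g in pd}

    # identity swaps: a pair of anticodon-similar tRNAs that exactly
    # exchanged placements
    swapped: set[str] = set()
    events: list[TranslocationEvent] = []
    for pair in IDENTITY_SWAP_PAIRS:
        a, b = sorted(pair)
        if a in moved and b in moved:
            if pa[a] == pd[b] and pa[b] == pd[a]:
                for g in (a, b):
                    events.append(
                        TranslocationEvent(
                            unit=(g,),
                            source=pa[g].describe(),
                            destination=pd[g].describe(),
                            destination_class=_unit_destination_class(
                                derived, (g,)
                            ),
                            inverted=pa[g].reversed != pd[g].reversed,
                            identity_swap=True,
                            species=(derived.taxon,),
                            genus=derived.genus,
                        )
                    )
                swapped |= {a, b}
    moved -= swapped

    units: list[tuple[str, ...]]
    if cluster_mode:
        units = _block_runs(moved, ancestor, derived)
    else:
        units = [(g,) for g in sorted(moved)]
    for unit in units:
        first, last = unit[0], unit[-1]
        events.append(
            TranslocationEvent(
                unit=unit,
                source=Placement(
                    pa[first].host,
                    pa[first].slot,
                    pa[first].up,
                    pa[last].down,
                    pa[first].reversed,
                ).describe(),
                destination=Placement(
                    pd[first].host,
                    pd[first].slot,
                    pd[first].up,
                    pd[last].down,
                    pd[first].reversed,
                ).describe(),
                destination_class=_unit_destination_class(derived, unit),
                inverted=pa[first].reversed != pd[first].reversed,
                identity_swap=False,
                species=(derived.taxon,),
                genus=derived.genus,
            )
        )
    return sorted(events, key=lambda e: e.unit)


def detect_events_min_variant(
    variants: Sequence[Karyotype],
    derived: Karyotype,
    cluster_mode: bool = True,
) -> tuple[list[TranslocationEvent], int, list[list[TranslocationEvent]]]:
    """Evaluate every equally parsimonious ancestral variant; report the
    event list of the variant minimising the (non-swap) event count, plus all
    per-variant lists for tie inspection."""
    per_variant = [
        detect_events(v, derived, cluster_mode) for v in variants
    ]
    counts = [sum(not e.identity_swap for e in evs) for evs in per_variant]
    best = min(range(len(variants)), key=lambda i: counts[i])
    return per_variant[best], best, per_variant


# ---------------------------------------------------------------------------
# Arrangement-pair tables (derived arrangements printed per species)


@dataclass(frozen=True)
class ArrangementPair:
    gene: str
    mrca_arrangement: str
    derived_arrangement: str
    species: str
    genus: str


def _strip(token: str) -> str:
    return token[1:] if token.startswith("~") else token


def classify_arrangement(gene: str, arrangement: str) -> str:
    tokens = [_strip(t) for t in arrangement.split("-") if t]
    if gene not in tokens:
        raise ValueError(
            f"malformed row: moving gene {gene!r} absent from "
            f"derived arrangement {arrangement!r}"
        )
    if tokens[0] == gene or tokens[-1] == gene:
        return DEST_ADJACENT
    return DEST_INTERGENIC


def detect_events_from_pairs(
    rows: Iterable[ArrangementPair],
) -> list[TranslocationEvent]:
    """One event per (row x species); destination class read off the string."""
    events = []
    for row in rows:
        events.append(
            TranslocationEvent(
                unit=(row.gene,),
                source=row.mrca_arrangement,
                destination=row.derived_arrangement,
                destination_class=classify_arrangement(
                    row.gene, row.derived_arrangement
                ),
                inverted=False,
                identity_swap=False,
                species=(row.species,),
                genus=row.genus,
            )
        )
    return events


def group_events(events: Iterable[TranslocationEvent]) -> list[EventGroup]:
    """Merge events shared by congeneric species with identical moving unit
    and destination; species of different genera never merge."""
    by_key: dict[tuple, list[TranslocationEvent]] = {}
    for e in sorted(events, key=lambda e: (e.unit, e.genus, e.destination, e.species)):
        by_key.setdefault(e.group_key(), []).append(e)
    groups = []
    for (genus, unit, destination), members in sorted(by_key.items()):
        groups.append(
            EventGroup(
                genus=genus,
                unit=unit,
                destination=destination,
                destination_class=members[0].destination_class,
                members=tuple(members),
            )
        )
    return groups
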