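"""Insertion-site census: expected vs observed NCR-adjacency of translocations.

The null model says a translocating tRNA unit lands uniformly on any
available insertion slot, so the expected probability of ending up adjacent
to the control region (NCR) is the fraction of available slots that flank an
NCR.  For a karyotype with G placed genes on M minichromosomes the raw slot
counts are ``adjacent = 2M``, ``intergenic = G - M``, ``total = G + M``.

Two adjustment conventions are implemented:

* ``T4`` (also used with an overridden base, tagged ``T6``): if the unit
  currently flanks the NCR, one adjacent slot is converted to an intergenic
  slot (moving the unit away frees its boundary slot but its old position
  becomes an internal one); a block of k tRNAs moving together removes k-1
  slots from the intergenic pool and the total.  Class counts always sum to
  the total.
* ``T8``: per-gene census that removes the unit's own slot from its class
  numerator; the denominator is ``total - 1`` when the unit flanks the NCR
  and ``total`` otherwise.  The two class fractions deliberately do not sum
  to one for intergenic residents -- the convention is reproduced as used,
  and reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .events import DEST_ADJACENT, DEST_INSIDE_NCR, EventGroup, TranslocationEvent, group_events
from .karyotype import Karyotype

CensusBase = tuple[int, int, int]  # (adjacent, intergenic, total)


@dataclass(frozen=True)
class SiteCensus:
    adjacent_slots: int
    intergenic_slots: int
    total_slots: int
    mode: str
    #: denominators actually used for the two probabilities (differ from
    #: total_slots only in T8 mode)
    adjacent_denominator: int
    intergenic_denominator: int

    @property
    def expected_adjacent_prob(self) -> float:
        return self.adjacent_slots / self.adjacent_denominator

    @property
    def expected_intergenic_prob(self) -> float:
        return self.intergenic_slots / self.intergenic_denominator


def base_counts(k: Karyotype) -> CensusBase:
    g = k.n_genes()
    m = len(k.minichromosomes)
    return (2 * m, g - m, g + m)


def _unit_flanks_ncr(k: Karyotype, unit: Sequence[str]) -> bool:
    mci, pos = k.find(unit[0])
    mc = k.minichromosomes[mci]
    names = mc.gene_names()
    if names[pos : pos + len(unit)] != tuple(unit):
        raise ValueError(f"unit {tuple(unit)} is not consecutive in {k.taxon}")
    return pos == 0 or pos + len(unit) == len(mc.genes)


def census_sites(
    k: Karyotype,
    unit: Sequence[str],
    mode: str = "T4",
    base_override: CensusBase | None = None,
) -> SiteCensus:
    """Available-slot census for a unit about to translocate out of ``k``."""
    if mode not in ("T4", "T6", "T8"):
        raise ValueError(f"unknown census mode {mode!r}")
    adj0, inter0, total0 = base_override if base_override else base_counts(k)
    flanks = _unit_flanks_ncr(k, unit)
    size = len(unit)
    if mode in ("T4", "T6"):
        adj, inter, total = adj0, inter0, total0
        if flanks:
            adj -= 1
            inter += 1
        if size > 1:
            total -= size - 1
            inter -= size - 1
        return SiteCensus(adj, inter, total, mode, total, total)
    # T8: single genes only
    if size > 1:
        raise ValueError("census mode T8 is defined for single-gene units")
    if flanks:
        adj, inter, denom = adj0 - 1, inter0, total0 - 1
    else:
        adj, inter, denom = adj0, inter0 - 1, total0
    return SiteCensus(adj, inter, total0, "T8", denom, denom)


@dataclass(frozen=True)
class AdjacencyRow:
    unit: tuple[str, ...]
    expected_adjacent_pct: float
    observed_adjacent_pct: float
    expected_intergenic_pct: float
    observed_intergenic_pct: float
    n_adjacent: int
    n_events: int
    census: SiteCensus

    def label(self) -> str:
        return "-".join(self.unit)


def adjacency_table(
    events: Iterable[TranslocationEvent],
    ancestor: Karyotype,
    mode: str = "T4",
    base_override: CensusBase | None = None,
    congeneric_grouping: bool = False,
) -> list[AdjacencyRow]:
    """One row per moving unit: expected (census) vs observed adjacency.

    With ``congeneric_grouping`` each genus-shared identical event counts
    once; otherwise every per-species event counts.  Identity swaps are
    excluded.  Units with zero remaining events are skipped.
    """
    items: list[EventGroup] | list[TranslocationEvent]
    events = [e for e in events if not e.identity_swap]
    if congeneric_grouping:
        items = group_events(events)
        keyed = [(g.unit, g.adjacent) for g in items]
    else:
        keyed = [
            (
                e.unit,
                e.destination_class in (DEST_ADJACENT, DEST_INSIDE_NCR),
            )
            for e in events
        ]
    rows = []
    for unit in sorted({u for u, _ in keyed}):
        hits = [adj for u, adj in keyed if u == unit]
        n = len(hits)
        n_adj = sum(hits)
        census = census_sites(ancestor, unit, mode, base_override)
        rows.append(
            AdjacencyRow(
                unit=unit,
                expected_adjacent_pct=100 * census.expected_adjacent_prob,
                observed_adjacent_pct=100 * n_adj / n,
                expected_intergenic_pct=100 * census.expected_intergenic_prob,
                observed_intergenic_pct=100 * (n - n_adj) / n,
                n_adjacent=n_adj,
                n_events=n,
                census=census,
            )
        )
    return rows
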