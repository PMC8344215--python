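"""Placement descriptors: where a gene sits relative to the backbone.

Two granularities are used:

* **slot-level** -- the host backbone plus the pair of backbone elements
  (coding gene or NCR end) flanking the gene's position.  Because backbone
  genes are unique genome-wide this identifies a position robustly even when
  *other* tRNAs move in or out next to the gene; it is the basis for deciding
  which tRNAs actually moved between two karyotypes.
* **neighbour-level** -- the immediate upstream/downstream element (which may
  itself be a tRNA).  This is the character state used for ancestral
  inference and the event source/destination descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genes import NCR
from .karyotype import BackboneKey, Karyotype, Minichromosome


@dataclass(frozen=True)
class Placement:
    """Full placement descriptor of one gene in one karyotype."""

    host: BackboneKey
    slot: tuple[str, str]  # flanking backbone elements (NCR for circle ends)
    up: str  # immediate upstream element (gene name or NCR)
    down: str  # immediate downstream element
    reversed: bool

    def neighbour_state(self) -> tuple:
        """The neighbour-level character state."""
        return (self.host, self.up, self.down, self.reversed)

    def slot_state(self) -> tuple:
        return (self.host, self.slot, self.reversed)

    def describe(self) -> str:
        host = "-".join(("~" if rev else "") + n for n, rev in self.host) or "(none)"
        orient = " (reversed)" if self.reversed else ""
        return f"{self.up}|{self.down} on {host}{orient}"


def _minichromosome_placements(mc: Minichromosome) -> dict[str, Placement]:
    host = mc.backbone()
    backbone_names = {name for name, _ in host}
    out: dict[str, Placement] = {}
    names = [g.name for g in mc.genes]
    # walk the circle, tracking the last-seen backbone element
    left_elements = []
    last = NCR
    for name in names:
        left_elements.append(last)
        if name in backbone_names:
            last = name
    right_elements = []
    nxt = NCR
    for name in reversed(names):
        right_elements.append(nxt)
        if name in backbone_names:
            nxt = name
    right_elements.reverse()
    for i, g in enumerate(mc.genes):
        up = names[i - 1] if i > 0 else NCR
        down = names[i + 1] if i < len(names) - 1 else NCR
        out[g.name] = Placement(
            host=host,
            slot=(left_elements[i], right_elements[i]),
            up=up,
            down=down,
            reversed=g.reversed,
        )
    return out


def placements(k: Karyotype) -> dict[str, Placement]:
    """Placement descriptor for every gene in the karyotype."""
    out: dict[str, Placement] = {}
    for mc in k.minichromosomes:
        out.update(_minichromosome_placements(mc))
    return out


def _lcs_keep(a: list[str], b: list[str]) -> set[str]:
    """Elements of a longest common subsequence of two orderings."""
    n, m = len(a), len(b)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if a[i] == b[j]:
                dp[i][j] = dp[i + 1][j + 1] + 1
            else:
                dp[i][j] = max(dp[i + 1][j], dp[i][j + 1])
    keep: set[str] = set()
    i = j = 0
    while i < n and j < m:
        if a[i] == b[j]:
            keep.add(a[i])
            i += 1
            j += 1
        elif dp[i + 1][j] >= dp[i][j + 1]:
            i += 1
        else:
            j += 1
    return keep


def moved_genes(a: Karyotype, b: Karyotype) -> set[str]:
    """The minimal set of genes whose placement differs between two karyotypes.

    A gene is moved when its slot-level placement (host backbone, flanking
    backbone elements, orientation) differs.  Genes sharing a slot in both
    karyotypes are additionally checked for order: if the within-slot order of
    the remaining genes differs, the smallest set breaking a longest common
    subsequence is marked moved as well.  Genes present in only one karyotype
    are ignored (missing, not moved).
    """
    pa, pb = placements(a), placements(b)
    common = set(pa) & set(pb)
    moved = {g for g in common if pa[g].slot_state() != pb[g].slot_state()}
    # within-slot order repair among the genes that stayed in their slot
    slots: dict[tuple, None] = {}
    for g in common - moved:
        slots.setdefault((pa[g].host, pa[g].slot), None)
    for host, slot in slots:
        in_a = [
            g.name
            for mc in a.minichromosomes
            if mc.backbone() == host
            for g in mc.genes
            if g.name in common - moved and pa[g.name].slot == slot
        ]
        in_b = [
            g.name
            for mc in b.minichromosomes
            if mc.backbone() == host
            for g in mc.genes
            if g.name in common - moved and pb[g.name].slot == slot
        ]
        if in_a != in_b:
            keep = _lcs_keep(in_a, in_b)
            moved |= set(in_a) - keep
    return moved
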