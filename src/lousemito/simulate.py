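"""Forward simulation of tRNA translocation on a fixed tree.

The process abstracts the rearrangement dynamics seen in fragmented louse
mitogenomes: per branch, a Poisson number of translocation events; each event
moves one tRNA (or an adjacent two-tRNA block) to a slot on a *different*
minichromosome, with a controllable bias towards NCR-adjacent destinations,
an optional orientation flip, and an optional per-branch anticodon identity
swap (L1/L2- or S1/S2-type).  Backbone genes never move and minichromosomes
never split or merge, matching the regime in which the translocation
statistics are defined.

The destination draw is a two-component mixture: with probability
``ncr_bias`` uniform over NCR-adjacent slots, otherwise uniform over all
available slots; the realized probability of an adjacent destination is
therefore ``ncr_bias + (1 - ncr_bias) * (adjacent slots / total slots)``.
Every simulated event is logged with enough detail that replaying the log on
the root karyotype reproduces each tip exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from .census import adjacency_table
from .events import detect_events
from .genes import IDENTITY_SWAP_PAIRS, GeneSymbol
from .karyotype import (
    MAX_GENES_PER_MINICHROMOSOME,
    Karyotype,
    Minichromosome,
    OrientedGene,
)
from .parsimony import PhylogenyTree
from .stats import pooled_t_test


@dataclass(frozen=True)
class EvolutionConfig:
    """Simulation parameters (all probabilities in [0, 1])."""

    event_rate: float = 0.5  # expected translocations per branch (Poisson)
    ncr_bias: float = 0.0  # 0 = uniform null, 1 = fully NCR-directed
    inversion_prob: float = 0.1  # per-event orientation flip
    cluster_prob: float = 0.1  # per-event chance of moving a 2-tRNA block
    swap_prob: float = 0.05  # per-branch chance of an identity swap
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ncr_bias", "inversion_prob", "cluster_prob", "swap_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.event_rate < 0:
            raise ValueError("event_rate must be >= 0")


@dataclass(frozen=True)
class EventRecord:
    """One logged simulation event, replayable."""

    kind: str  # "move" | "swap"
    unit: tuple[str, ...]
    source_minichromosome: int = -1
    source_position: int = -1
    dest_minichromosome: int = -1
    dest_position: int = -1
    inverted: bool = False
    dest_class: str = ""
    #: slot availability at draw time, for the census oracle
    n_adjacent_available: int = 0
    n_total_available: int = 0


@dataclass
class SimulatedDataset:
    root: Karyotype
    tips: dict[str, Karyotype]
    #: per-branch log, keyed by the branch's child clade (sorted leaf labels)
    log: dict[tuple[str, ...], list[EventRecord]]
    config: EvolutionConfig


def _as_lists(k: Karyotype) -> list[list[OrientedGene]]:
    return [list(mc.genes) for mc in k.minichromosomes]


def _from_lists(k: Karyotype, lists: list[list[OrientedGene]], taxon: str) -> Karyotype:
    minis = tuple(Minichromosome(tuple(genes)) for genes in lists)
    return Karyotype(taxon=taxon, genus=k.genus, minichromosomes=minis)


def apply_event(lists: list[list[OrientedGene]], rec: EventRecord) -> None:
    """Apply one logged event in place (replay primitive)."""
    if rec.kind == "swap":
        a, b = rec.unit
        pos = {}
        for mi, genes in enumerate(lists):
            for gi, g in enumerate(genes):
                if g.name in (a, b):
                    pos[g.name] = (mi, gi)
        (ma, ia), (mb, ib) = pos[a], pos[b]
        ga, gb = lists[ma][ia], lists[mb][ib]
        lists[ma][ia] = OrientedGene(GeneSymbol(b), ga.reversed)
        lists[mb][ib] = OrientedGene(GeneSymbol(a), gb.reversed)
        return
    src = lists[rec.source_minichromosome]
    size = len(rec.unit)
    block = src[rec.source_position : rec.source_position + size]
    assert tuple(g.name for g in block) == rec.unit
    del src[rec.source_position : rec.source_position + size]
    if rec.inverted:
        block = [g.flipped() for g in reversed(block)]
    dest = lists[rec.dest_minichromosome]
    lists[rec.dest_minichromosome] = (
        dest[: rec.dest_position] + block + dest[rec.dest_position :]
    )


def draw_event(
    lists: list[list[OrientedGene]],
    rng: np.random.Generator,
    config: EvolutionConfig,
) -> EventRecord:
    """Draw one translocation on the current state (no swap)."""
    # choose the moving unit
    trna_positions = [
        (mi, gi)
        for mi, genes in enumerate(lists)
        for gi, g in enumerate(genes)
        if g.gene.is_trna
    ]
    if not trna_positions:
        raise ValueError("karyotype has no tRNA genes to move")
    unit_pos: tuple[int, int]
    size = 1
    if config.cluster_prob > 0 and rng.random() < config.cluster_prob:
        pairs = [
            (mi, gi)
            for mi, genes in enumerate(lists)
            for gi in range(len(genes) - 1)
            if genes[gi].gene.is_trna
            and genes[gi + 1].gene.is_trna
            and genes[gi].reversed == genes[gi + 1].reversed
        ]
        if pairs:
            unit_pos = pairs[rng.integers(len(pairs))]
            size = 2
        else:
            unit_pos = trna_positions[rng.integers(len(trna_positions))]
    else:
        unit_pos = trna_positions[rng.integers(len(trna_positions))]
    mi, gi = unit_pos
    unit = tuple(g.name for g in lists[mi][gi : gi + size])

    # enumerate destination slots on other minichromosomes
    slots: list[tuple[int, int]] = []
    adjacent: list[tuple[int, int]] = []
    for mj, genes in enumerate(lists):
        if mj == mi:
            continue
        if len(genes) + size > MAX_GENES_PER_MINICHROMOSOME:
            continue
        for pos in range(len(genes) + 1):
            slots.append((mj, pos))
            if pos == 0 or pos == len(genes):
                adjacent.append((mj, pos))
    if not slots:
        raise ValueError("no eligible destination slot (degenerate karyotype)")
    if config.ncr_bias > 0 and rng.random() < config.ncr_bias:
        mj, pos = adjacent[rng.integers(len(adjacent))]
    else:
        mj, pos = slots[rng.integers(len(slots))]
    inverted = bool(rng.random() < config.inversion_prob)
    dest_len = len(lists[mj])
    dest_class = "adjacent" if (pos == 0 or pos == dest_len) else "intergenic"
    return EventRecord(
        kind="move",
        unit=unit,
        source_minichromosome=mi,
        source_position=gi,
        dest_minichromosome=mj,
        dest_position=pos,
        inverted=inverted,
        dest_class=dest_class,
        n_adjacent_available=len(adjacent),
        n_total_available=len(slots),
    )


def simulate_branch(
    k: Karyotype,
    config: EvolutionConfig,
    rng: np.random.Generator,
    taxon: str | None = None,
) -> tuple[Karyotype, list[EventRecord]]:
    """Evolve a karyotype along one branch; returns (result, event log)."""
    lists = _as_lists(k)
    log: list[EventRecord] = []
    n_events = int(rng.poisson(config.event_rate))
    for _ in range(n_events):
        rec = draw_event(lists, rng, config)
        apply_event(lists, rec)
        log.append(rec)
    if config.swap_prob > 0 and rng.random() < config.swap_prob:
        present = {g.name for genes in lists for g in genes}
        eligible = [
            tuple(sorted(p)) for p in IDENTITY_SWAP_PAIRS if p <= present
        ]
        if eligible:
            pair = eligible[rng.integers(len(eligible))]
            rec = EventRecord(kind="swap", unit=pair)
            apply_event(lists, rec)
            log.append(rec)
    return _from_lists(k, lists, taxon or k.taxon), log


def _branch_rng(seed: int, clade: tuple[str, ...]) -> np.random.Generator:
    """Deterministic per-branch stream, stable under tree extension."""
    digest = hashlib.sha256(
        (str(seed) + "|" + "|".join(clade)).encode()
    ).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "big"))


def simulate_tree(
    tree: PhylogenyTree, root: Karyotype, config: EvolutionConfig
) -> SimulatedDataset:
    """Depth-first simulation from the root karyotype down to every leaf."""
    tips: dict[str, Karyotype] = {}
    log: dict[tuple[str, ...], list[EventRecord]] = {}

    def clade_of(node) -> tuple[str, ...]:
        return tuple(sorted(leaf.taxon.label for leaf in node.leaf_iter()))

    def walk(node, k: Karyotype) -> None:
        for child in node.child_nodes():
            clade = clade_of(child)
            rng = _branch_rng(config.seed, clade)
            child_k, branch_log = simulate_branch(
                k, config, rng, taxon="/".join(clade)
            )
            log[clade] = branch_log
            if child.is_leaf():
                tips[child.taxon.label] = replace(
                    child_k, taxon=child.taxon.label
                )
            else:
                walk(child, child_k)

    walk(tree.tree.seed_node, root)
    return SimulatedDataset(root=root, tips=tips, log=log, config=config)


def replay(root: Karyotype, records: list[EventRecord], taxon: str = "replayed") -> Karyotype:
    lists = _as_lists(root)
    for rec in records:
        apply_event(lists, rec)
    return _from_lists(root, lists, taxon)


def replay_tip(dataset: SimulatedDataset, tip: str) -> Karyotype:
    """Replay the root-to-tip event log for one leaf (ledger soundness)."""
    tree_logs = [
        (clade, recs) for clade, recs in dataset.log.items() if tip in clade
    ]
    # root-to-tip order = decreasing clade size
    tree_logs.sort(key=lambda item: -len(item[0]))
    records = [rec for _, recs in tree_logs for rec in recs]
    return replay(dataset.root, records, taxon=tip)


# ---------------------------------------------------------------------------
# Calibration of the adjacency statistics


@dataclass
class CalibrationReport:
    replicates: int
    tested: int  # replicates yielding a testable (>= 2 unit) table
    rejections: int
    alpha: float
    rejection_rate: float
    rejection_ci95: tuple[float, float]
    mean_observed_adjacent_pct: float
    mean_event_count: float
    config: EvolutionConfig


def calibration_experiment(
    tree: PhylogenyTree,
    root: Karyotype,
    config: EvolutionConfig,
    replicates: int,
    alpha: float = 0.05,
) -> CalibrationReport:
    """Monte-Carlo check of the expected-vs-observed adjacency t-test.

    Each replicate simulates tip karyotypes, detects events against the true
    root, builds the per-unit adjacency table (T4 census on the root) and
    applies the pooled t-test to its expected/observed adjacent columns.
    Reports the rejection rate at ``alpha`` with a Clopper-Pearson 95% CI and
    the mean observed adjacency.  Note the test treats per-unit rows as
    independent observations -- the same convention as the analysis it
    calibrates -- so its null size need not equal ``alpha`` exactly.
    """
    from scipy.stats import binomtest

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    tested = rejections = 0
    adj_fractions: list[float] = []
    event_counts: list[int] = []
    for rep in range(replicates):
        rep_config = replace(config, seed=(config.seed * 1_000_003 + rep) % 2**31)
        dataset = simulate_tree(tree, root, rep_config)
        all_events = []
        for tip_k in dataset.tips.values():
            all_events.extend(detect_events(root, tip_k, cluster_mode=True))
        real = [e for e in all_events if not e.identity_swap]
        event_counts.append(len(real))
        if real:
            adj = sum(e.destination_class != "intergenic" for e in real)
            adj_fractions.append(100 * adj / len(real))
        rows = adjacency_table(real, root, mode="T4")
        if len(rows) < 2:
            continue
        tested += 1
        res = pooled_t_test(
            [r.expected_adjacent_pct for r in rows],
            [r.observed_adjacent_pct for r in rows],
        )
        if res.p_two_tailed < alpha:
            rejections += 1
    rate = rejections / tested if tested else float("nan")
    if tested:
        ci = binomtest(rejections, tested).proportion_ci(confidence_level=0.95)
        ci_pair = (ci.low, ci.high)
    else:
        ci_pair = (float("nan"), float("nan"))
    return CalibrationReport(
        replicates=replicates,
        tested=tested,
        rejections=rejections,
        alpha=alpha,
        rejection_rate=rate,
        rejection_ci95=ci_pair,
        mean_observed_adjacent_pct=(
            sum(adj_fractions) / len(adj_fractions) if adj_fractions else float("nan")
        ),
        mean_event_count=sum(event_counts) / len(event_counts),
        config=config,
    )
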