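"""Exact stochastic simulation of the Log-DDG diversification process.

Between events every rate is constant (richness only changes when an
event fires), so the process is simulated exactly with the Gillespie
algorithm: draw an exponential waiting time from the summed per-lineage
rates, pick one event proportionally to its rate, apply it, update the
regional richness vector, repeat.

Event semantics (GeoSSE with diversity dependence):

* within-region speciation in region i — the parent keeps its range and
  buds a daughter with range {i};
* between-region speciation — the parent is replaced by two daughters
  whose ranges (k, l) bipartition the parent range;
* dispersal i -> j — region j is added to the actor's range;
* extinction in region i — region i is removed from the actor's range;
  if the range was {i} the lineage dies (global extinction).

The full tree (extinct lineages included) is returned; use
:func:`prune_to_extant` for the reconstructed extant-only timetree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .model import DDParams, LineageRates, census, lineage_event_rates

__all__ = [
    "Lineage",
    "EventRecord",
    "StopCondition",
    "SimTree",
    "simulate",
    "replay_events",
    "prune_to_extant",
    "richness_trajectory",
    "n_extant",
    "tree_height",
]

Range = FrozenSet[int]

WITHIN = "within-speciation"
BETWEEN = "between-speciation"
DISPERSAL = "dispersal"
CONTRACTION = "range-contraction"
EXTINCTION = "global-extinction"


@dataclass
class Lineage:
    id: int
    parent: Optional[int]
    birth: float
    death: Optional[float] = None
    range_: Range = frozenset()
    alive: bool = True
    # True when the lineage terminated by splitting into two daughters
    # (it leaves no tip in the tree), False when it went extinct.
    split: bool = False


@dataclass(frozen=True)
class EventRecord:
    time: float
    kind: str
    lineage: int
    # region index for within/contraction/extinction, (i, j) for
    # dispersal, (k, l) range pair for between-region speciation
    detail: object
    daughters: Tuple[int, ...] = ()


@dataclass(frozen=True)
class StopCondition:
    """When to stop a simulation.

    ``max_time`` is always enforced; if ``max_taxa`` is set the run also
    stops at the first event at which the extant count reaches the cap
    (that event is kept and the stop time is that event's time).
    ``min_taxa`` is a post-hoc acceptance threshold used by rejection
    samplers, not a stopping rule.
    """

    max_time: float
    max_taxa: Optional[int] = None
    min_taxa: int = 1

    def __post_init__(self) -> None:
        if self.max_time <= 0:
            raise ValueError("max_time must be > 0")
        if self.min_taxa < 1:
            raise ValueError("min_taxa must be >= 1")


@dataclass
class SimTree:
    """A simulated Log-DDG realization: lineage table plus event log."""

    params: DDParams
    lineages: List[Lineage]
    events: List[EventRecord]
    root_range: Range
    final_time: float
    # total per-lineage event rate hit exactly zero with extant lineages
    absorbed: bool = False

    @property
    def n_regions(self) -> int:
        return self.params.n_regions

    @property
    def extant(self) -> List[Lineage]:
        return [ln for ln in self.lineages if ln.alive]

    @property
    def all_extinct(self) -> bool:
        return not any(ln.alive for ln in self.lineages)

    def richness(self) -> np.ndarray:
        """Regional richness censused from the extant lineage table."""
        return census([ln.range_ for ln in self.extant], self.n_regions)


def _lineage_rate_tables(
    extant: Sequence[Lineage], n: np.ndarray, params: DDParams
) -> Dict[Range, LineageRates]:
    # lineages sharing a range have identical rate tables; computing one
    # table per distinct range keeps each Gillespie step cheap
    tables: Dict[Range, LineageRates] = {}
    for ln in extant:
        if ln.range_ not in tables:
            tables[ln.range_] = lineage_event_rates(ln.range_, n, params)
    return tables


def _pick_event(
    extant: Sequence[Lineage],
    tables: Dict[Range, LineageRates],
    total: float,
    u: float,
) -> Tuple[Lineage, str, object]:
    # single uniform draw over the cumulative rate table, walking
    # lineages in id order and event entries in their fixed order
    target = u * total
    acc = 0.0
    for ln in extant:
        t = tables[ln.range_]
        ln_total = t.total
        if acc + ln_total < target:
            acc += ln_total
            continue
        for kind, entries in (
            (WITHIN, t.within),
            (CONTRACTION, t.extinction),
            (DISPERSAL, t.dispersal),
            (BETWEEN, t.between),
        ):
            for key, rate in entries:
                acc += rate
                if acc >= target:
                    return ln, kind, key
        # float roundoff landed past this lineage's entries
        kind, key = _last_entry(t)
        return ln, kind, key
    # roundoff landed past the whole table: last entry of last lineage
    ln = extant[-1]
    kind, key = _last_entry(tables[ln.range_])
    return ln, kind, key


def _last_entry(t: LineageRates) -> Tuple[str, object]:
    for kind, entries in (
        (BETWEEN, t.between),
        (DISPERSAL, t.dispersal),
        (CONTRACTION, t.extinction),
        (WITHIN, t.within),
    ):
        if entries:
            return kind, entries[-1][0]
    raise RuntimeError("empty rate table")


def simulate(
    params: DDParams,
    stop: StopCondition,
    root_range: Range | Sequence[int] = frozenset({0}),
    seed: int | np.random.Generator | None = None,
) -> SimTree:
    """Run one exact realization of the Log-DDG process.

    Starts from a single root lineage with ``root_range`` at time 0 and
    returns the full tree with every extinct lineage and the complete
    event log.  Deterministic given the seed.
    """
    root_range = frozenset(root_range)
    if not root_range:
        raise ValueError("root range must be nonempty")
    if not root_range <= set(params.regions):
        raise ValueError("root range outside the region set")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    lineages = [Lineage(id=0, parent=None, birth=0.0, range_=root_range)]
    extant: List[Lineage] = [lineages[0]]
    n = census([root_range], params.n_regions)
    events: List[EventRecord] = []
    t = 0.0
    absorbed = False

    while True:
        if not extant:
            break
        if stop.max_taxa is not None and len(extant) >= stop.max_taxa:
            break
        tables = _lineage_rate_tables(extant, n, params)
        total = sum(tables[ln.range_].total for ln in extant)
        if total <= 0.0:
            absorbed = True
            break
        wait = rng.exponential(1.0 / total)
        if t + wait > stop.max_time:
            break
        t += wait
        ln, kind, key = _pick_event(extant, tables, total, rng.random())

        if kind == WITHIN:
            i = key
            daughter = Lineage(
                id=len(lineages), parent=ln.id, birth=t, range_=frozenset({i})
            )
            lineages.append(daughter)
            extant.append(daughter)
            n[i] += 1
            events.append(EventRecord(t, WITHIN, ln.id, i, (daughter.id,)))
        elif kind == DISPERSAL:
            i, j = key
            ln.range_ = ln.range_ | {j}
            n[j] += 1
            events.append(EventRecord(t, DISPERSAL, ln.id, (i, j)))
        elif kind == CONTRACTION:
            i = key
            new_range = ln.range_ - {i}
            n[i] -= 1
            if new_range:
                ln.range_ = new_range
                events.append(EventRecord(t, CONTRACTION, ln.id, i))
            else:
                ln.alive = False
                ln.death = t
                extant.remove(ln)
                events.append(EventRecord(t, EXTINCTION, ln.id, i))
        else:  # BETWEEN
            k, l = key
            d1 = Lineage(id=len(lineages), parent=ln.id, birth=t, range_=k)
            d2 = Lineage(id=len(lineages) + 1, parent=ln.id, birth=t, range_=l)
            lineages.extend((d1, d2))
            ln.alive = False
            ln.death = t
            ln.split = True
            extant.remove(ln)
            extant.extend((d1, d2))
            # richness unchanged: k and l partition the parent range
            events.append(EventRecord(t, BETWEEN, ln.id, (k, l), (d1.id, d2.id)))

    if not extant:
        final_time = t  # full extinction: the tree ends at the last death
    elif stop.max_taxa is not None and len(extant) >= stop.max_taxa:
        final_time = t  # taxon cap reached: stop at that event's time
    else:
        # ran to max_time (an absorbed state persists unchanged to it)
        final_time = stop.max_time
    return SimTree(
        params=params,
        lineages=lineages,
        events=events,
        root_range=root_range,
        final_time=final_time,
        absorbed=absorbed,
    )


def replay_events(tree: SimTree) -> List[Lineage]:
    """Re-derive the final lineage table by replaying the event log.

    Starts from a fresh root with the recorded root range and applies
    every event in order; used to check the state-replay identity.
    """
    lineages = [Lineage(id=0, parent=None, birth=0.0, range_=tree.root_range)]
    by_id = {0: lineages[0]}
    for ev in tree.events:
        ln = by_id[ev.lineage]
        if ev.kind == WITHIN:
            (did,) = ev.daughters
            d = Lineage(id=did, parent=ln.id, birth=ev.time, range_=frozenset({ev.detail}))
            lineages.append(d)
            by_id[did] = d
        elif ev.kind == DISPERSAL:
            _, j = ev.detail
            ln.range_ = ln.range_ | {j}
        elif ev.kind == CONTRACTION:
            ln.range_ = ln.range_ - {ev.detail}
        elif ev.kind == EXTINCTION:
            ln.alive = False
            ln.death = ev.time
        elif ev.kind == BETWEEN:
            k, l = ev.detail
            ln.alive = False
            ln.death = ev.time
            ln.split = True
            for did, rng_ in zip(ev.daughters, (k, l)):
                d = Lineage(id=did, parent=ln.id, birth=ev.time, range_=rng_)
                lineages.append(d)
                by_id[did] = d
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
    return lineages


def tip_label(lineage_id: int) -> str:
    return f"s{lineage_id}"


def to_dendropy(tree: SimTree, include_extinct: bool = True) -> dendropy.Tree:
    """Convert the lineage table to a dendropy tree.

    Each lineage is a branch from its birth to its end (death or the
    final time); daughters attach at their birth times, subdividing the
    parent branch into segments.  Extant tips are labelled ``s<id>``
    and extinct tips ``x<id>``.
    """
    children: Dict[int, List[Lineage]] = {ln.id: [] for ln in tree.lineages}
    for ln in tree.lineages:
        if ln.parent is not None:
            children[ln.parent].append(ln)
    for kids in children.values():
        kids.sort(key=lambda ln: (ln.birth, ln.id))

    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)
    # explicit stack; recursion depth would scale with tree depth
    stack: List[Tuple[Lineage, dendropy.Node]] = [(tree.lineages[0], dtree.seed_node)]
    dtree.seed_node.edge.length = 0.0
    while stack:
        ln, attach = stack.pop()
        t_prev = ln.birth
        node = attach
        kids = children[ln.id]
        end = ln.death if ln.death is not None else tree.final_time
        if ln.split:
            # the final two daughters share the death time; the last
            # node on the spine carries them both and no tip
            budding, split_pair = kids[:-2], kids[-2:]
        else:
            budding, split_pair = kids, []
        for child in budding:
            inner = dendropy.Node()
            inner.edge.length = child.birth - t_prev
            node.add_child(inner)
            stack.append((child, inner))
            node = inner
            t_prev = child.birth
        if ln.split:
            inner = dendropy.Node()
            inner.edge.length = end - t_prev
            node.add_child(inner)
            for child in split_pair:
                stack.append((child, inner))
        else:
            label = tip_label(ln.id) if ln.alive else f"x{ln.id}"
            tip = dendropy.Node()
            tip.taxon = taxa.new_taxon(label)
            tip.edge.length = end - t_prev
            node.add_child(tip)
    if not include_extinct:
        keep = [tx for tx in taxa if tx.label.startswith("s")]
        if not keep:
            raise ValueError("tree is fully extinct; no extant tips to keep")
        dtree = dtree.extract_tree_with_taxa(taxa=keep)
        dtree.purge_taxon_namespace()
    return dtree


def prune_to_extant(tree: SimTree) -> dendropy.Tree:
    """Reconstructed extant-only timetree.

    Extinct lineages are removed and the resulting unifurcations
    suppressed (branch lengths merged).  Raises if no lineage survives.
    """
    if tree.all_extinct:
        raise ValueError("cannot prune: the tree went completely extinct")
    return to_dendropy(tree, include_extinct=False)


def richness_trajectory(tree: SimTree) -> Tuple[np.ndarray, np.ndarray]:
    """Per-region richness as a right-continuous step function of time.

    Returns ``(times, counts)`` where ``times`` has length E + 2 (the
    origin, every event time, and the final time) and ``counts`` is the
    matching (E + 2, n_regions) array of regional species counts.
    """
    n = census([tree.root_range], tree.n_regions).astype(np.int64)
    times = [0.0]
    counts = [n.copy()]
    lineages = {0: frozenset(tree.root_range)}
    for ev in tree.events:
        if ev.kind == WITHIN:
            n[ev.detail] += 1
            lineages[ev.daughters[0]] = frozenset({ev.detail})
        elif ev.kind == DISPERSAL:
            _, j = ev.detail
            n[j] += 1
            lineages[ev.lineage] = lineages[ev.lineage] | {j}
        elif ev.kind in (CONTRACTION, EXTINCTION):
            n[ev.detail] -= 1
            lineages[ev.lineage] = lineages[ev.lineage] - {ev.detail}
        elif ev.kind == BETWEEN:
            k, l = ev.detail
            lineages[ev.daughters[0]] = k
            lineages[ev.daughters[1]] = l
        times.append(ev.time)
        counts.append(n.copy())
    times.append(tree.final_time)
    counts.append(n.copy())
    return np.asarray(times), np.vstack(counts)


def n_extant(tree: SimTree) -> int:
    """Number of extant lineages at the final time."""
    return len(tree.extant)


def tree_height(tree: SimTree) -> float:
    """Time from the origin to the latest tip (death or final time)."""
    ends = [ln.death if ln.death is not None else tree.final_time for ln in tree.lineages]
    return max(ends) if ends else 0.0
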