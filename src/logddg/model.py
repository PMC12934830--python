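"""Core Log-DDG rate model.

The Log-DDG model is a diversity-dependent extension of GeoSSE: each
lineage carries a geographic range (a nonempty subset of discrete
regions) and experiences within-region speciation, between-region
(allopatric) speciation, dispersal, and per-region extinction.  Each
process rate is a base rate multiplied by a diversity-dependent factor

    m_p(x) = (ln x + 1) ** p

where ``x`` is a local species count and ``p`` a real-valued effect
exponent.  The logarithm makes diversity act on orders of magnitude of
richness rather than on raw counts; ``p = 0`` or ``x = 1`` recovers the
diversity-independent (classic GeoSSE) base rate exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import FrozenSet, Iterator, Sequence, Tuple

import numpy as np

__all__ = [
    "DDParams",
    "SubmodelSpec",
    "log_rate_factor",
    "extinction_rate",
    "within_speciation_rate",
    "dispersal_rate",
    "between_edge_weight",
    "cut_set",
    "split_score",
    "between_region_rate",
    "range_bipartitions",
    "lineage_event_rates",
    "LineageRates",
]

Range = FrozenSet[int]


@dataclass(frozen=True)
class DDParams:
    """Parameters of a Log-DDG model.

    Base rates are per-lineage event rates (events per unit time);
    effect exponents control the sign and strength of the influence of
    local species richness on each process (negative = suppression,
    positive = amplification, zero = none).

    Parameters
    ----------
    rho_w, rho_e, rho_d, rho_b
        Base rates of within-region speciation, per-region extinction,
        dispersal, and between-region speciation.  All must be >= 0.
    w_D, e_D, d_D_src, d_D_dest, b_D
        Diversity-dependent effect exponents for within-region
        speciation, extinction, outbound dispersal (source richness),
        inbound dispersal (destination richness), and between-region
        speciation (edge weights of the range-split graph).
    n_regions
        Number of discrete regions, >= 2.
    """

    rho_w: float
    rho_e: float
    rho_d: float
    rho_b: float
    w_D: float = 0.0
    e_D: float = 0.0
    d_D_src: float = 0.0
    d_D_dest: float = 0.0
    b_D: float = 0.0
    n_regions: int = 2

    def __post_init__(self) -> None:
        for name in ("rho_w", "rho_e", "rho_d", "rho_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"base rate {name} must be >= 0")
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")

    @property
    def regions(self) -> range:
        return range(self.n_regions)

    @property
    def submodel_id(self) -> int:
        """Submodel index 0-7 from which of (e_D, w_D, d_D_dest) are active.

        Bit 0 = diversity-dependent extinction, bit 1 = within-region
        speciation, bit 2 = inbound dispersal; e.g. 7 means all three.
        """
        return (
            (1 if self.e_D != 0 else 0)
            + (2 if self.w_D != 0 else 0)
            + (4 if self.d_D_dest != 0 else 0)
        )


@dataclass(frozen=True)
class SubmodelSpec:
    """Which processes carry a diversity-dependent effect.

    Maps bijectively onto the eight canonical submodels (0 = none,
    7 = extinction + within-region speciation + inbound dispersal).
    Outbound dispersal and between-region speciation are always
    diversity-independent in this scheme.
    """

    dd_extinction: bool = False
    dd_within_speciation: bool = False
    dd_dispersal_dest: bool = False

    @property
    def submodel_id(self) -> int:
        return (
            (1 if self.dd_extinction else 0)
            + (2 if self.dd_within_speciation else 0)
            + (4 if self.dd_dispersal_dest else 0)
        )

    @classmethod
    def from_id(cls, submodel_id: int) -> "SubmodelSpec":
        if not 0 <= submodel_id <= 7:
            raise ValueError("submodel id must be in 0..7")
        return cls(
            dd_extinction=bool(submodel_id & 1),
            dd_within_speciation=bool(submodel_id & 2),
            dd_dispersal_dest=bool(submodel_id & 4),
        )


def log_rate_factor(x: float, p: float) -> float:
    """Diversity-dependent rate factor ``(ln x + 1) ** p``.

    ``x`` is a (possibly composite) species count: callers pass ``n_i``
    for extinction / within-region speciation / dispersal source,
    ``n_j + 1`` for the dispersal destination, and ``n_i * n_j`` for
    range-split edge weights.  Equals 1 exactly when ``x == 1`` (the
    lineage is alone) or ``p == 0`` (no effect).
    """
    if x < 1:
        raise ValueError(f"count argument must be >= 1, got {x}")
    return (math.log(x) + 1.0) ** p


def _check_region(i: int, params: DDParams) -> None:
    if not 0 <= i < params.n_regions:
        raise ValueError(f"region index {i} outside 0..{params.n_regions - 1}")


def extinction_rate(i: int, n: Sequence[int], params: DDParams) -> float:
    """Per-lineage extinction (range-contraction) rate in region ``i``."""
    _check_region(i, params)
    if n[i] < 1:
        raise ValueError(f"extinction rate undefined: region {i} has no species")
    return params.rho_e * log_rate_factor(n[i], params.e_D)


def within_speciation_rate(i: int, n: Sequence[int], params: DDParams) -> float:
    """Per-lineage within-region (budding) speciation rate in region ``i``."""
    _check_region(i, params)
    if n[i] < 1:
        raise ValueError(f"within-region speciation undefined: region {i} empty")
    return params.rho_w * log_rate_factor(n[i], params.w_D)


def dispersal_rate(i: int, j: int, n: Sequence[int], params: DDParams) -> float:
    """Per-lineage dispersal rate from occupied region ``i`` into ``j``.

    The source factor uses the source richness ``n_i``; the destination
    factor uses ``n_j + 1`` so that an empty destination (``n_j = 0``)
    contributes no diversity-dependent effect.
    """
    _check_region(i, params)
    _check_region(j, params)
    if i == j:
        raise ValueError("dispersal requires distinct source and destination")
    if n[i] < 1:
        raise ValueError(f"dispersal undefined: source region {i} has no species")
    return (
        params.rho_d
        * log_rate_factor(n[i], params.d_D_src)
        * log_rate_factor(n[j] + 1, params.d_D_dest)
    )


def between_edge_weight(i: int, j: int, n: Sequence[int], params: DDParams) -> float:
    """Connectivity weight of the region pair (i, j) for range splits.

    ``(ln(n_i * n_j) + 1) ** b_D``; symmetric in (i, j) and equal to 1
    when both counts are 1 or the effect is off.
    """
    if n[i] < 1 or n[j] < 1:
        raise ValueError("split edge weight requires both regions occupied")
    return log_rate_factor(n[i] * n[j], params.b_D)


def cut_set(k: Range, l: Range) -> FrozenSet[Tuple[int, int]]:
    """Minimal edge set separating ranges ``k`` and ``l``.

    Regions form a complete graph (no adjacency constraints), so the
    cut is the full bipartite cross product; ``|cut| = |k| * |l|``.
    """
    k, l = frozenset(k), frozenset(l)
    if not k or not l:
        raise ValueError("both parts of a range split must be nonempty")
    if k & l:
        raise ValueError(f"range split parts overlap: {sorted(k & l)}")
    return frozenset((i, j) for i in k for j in l)


def split_score(k: Range, l: Range, n: Sequence[int], params: DDParams) -> float:
    """Range-split score f_b for the bipartition (k, l) of a parent range.

    The inverse of the sum of inverse mean edge weights over the cut
    set: with all edge weights 1 this is ``1 / (|k| * |l|)``, and for a
    single-edge cut with unit weight it is exactly 1 (so the
    between-region rate reduces to the base rate).
    """
    edges = cut_set(k, l)
    inv_sum = 0.0
    for i, j in edges:
        w = 0.5 * (
            between_edge_weight(i, j, n, params) + between_edge_weight(j, i, n, params)
        )
        inv_sum += 1.0 / w
    return 1.0 / inv_sum


def between_region_rate(k: Range, l: Range, n: Sequence[int], params: DDParams) -> float:
    """Rate of allopatric speciation splitting a range into (k, l)."""
    return params.rho_b * split_score(k, l, n, params)


def range_bipartitions(rng: Range) -> Iterator[Tuple[Range, Range]]:
    """Unordered bipartitions {k, l} of a range into nonempty parts.

    A range of size m has ``2**(m-1) - 1`` of them; a single-region
    range has none.  Deterministic order: anchored on the smallest
    region index so each unordered pair appears exactly once.
    """
    members = sorted(rng)
    if len(members) < 2:
        return
    anchor, rest = members[0], members[1:]
    for r in range(0, len(rest)):
        for extra in combinations(rest, r):
            k = frozenset((anchor, *extra))
            l = frozenset(rng) - k
            if l:
                yield k, l


@dataclass
class LineageRates:
    """Per-event-type rate table for a single lineage.

    Entries are (key, rate) lists in a fixed deterministic order:
    within-region speciation and extinction per occupied region
    (ascending region index), dispersal per (source, destination) pair,
    and between-region speciation per unordered bipartition of the
    range (empty when the range is a single region).
    """

    within: list = field(default_factory=list)       # [(i, rate)]
    extinction: list = field(default_factory=list)   # [(i, rate)]
    dispersal: list = field(default_factory=list)    # [((i, j), rate)]
    between: list = field(default_factory=list)      # [((k, l), rate)]

    @property
    def total(self) -> float:
        return (
            sum(r for _, r in self.within)
            + sum(r for _, r in self.extinction)
            + sum(r for _, r in self.dispersal)
            + sum(r for _, r in self.between)
        )


def lineage_event_rates(rng: Range, n: Sequence[int], params: DDParams) -> LineageRates:
    """All event rates experienced by one lineage with range ``rng``.

    The richness vector ``n`` must be consistent (every occupied region
    has ``n_i >= 1``).
    """
    rng = frozenset(rng)
    if not rng:
        raise ValueError("lineage range must be nonempty")
    occupied = sorted(rng)
    unoccupied = [j for j in params.regions if j not in rng]
    rates = LineageRates()
    for i in occupied:
        rates.within.append((i, within_speciation_rate(i, n, params)))
        rates.extinction.append((i, extinction_rate(i, n, params)))
    for i in occupied:
        for j in unoccupied:
            rates.dispersal.append(((i, j), dispersal_rate(i, j, n, params)))
    if len(rng) >= 2:
        for k, l in range_bipartitions(rng):
            rates.between.append(((k, l), between_region_rate(k, l, n, params)))
    return rates


def census(ranges: Sequence[Range], n_regions: int) -> np.ndarray:
    """Regional richness vector from a collection of extant ranges."""
    n = np.zeros(n_regions, dtype=np.int64)
    for rng in ranges:
        for i in rng:
            n[i] += 1
    return n
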