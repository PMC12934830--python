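"""Tree-shape and range summary statistics for Log-DDG simulations.

Implements the Pybus–Harvey γ statistic (node-depth distribution of an
ultrametric tree), the maximum-likelihood Aldous β of the
beta-splitting topology model (tree balance; 0 = Yule, −2 = maximally
imbalanced), mean geographic range size across tips, and treeness (the
proportion of total branch length contributed by internal branches) —
plus the mesh-grid simulation study that maps how these statistics
respond to diversity-dependent effect strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterator, List, Optional, Tuple

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .model import DDParams
from .simulate import SimTree, StopCondition, n_extant, prune_to_extant, simulate

__all__ = [
    "TreeStatSummary",
    "GridDesign",
    "gamma_statistic",
    "beta_statistic",
    "mean_range_size",
    "treeness",
    "summarize_tree",
    "grid_design_tree_count",
    "run_grid_study",
]

BETA_LOWER = -2.0
BETA_UPPER = 10.0


@dataclass(frozen=True)
class TreeStatSummary:
    beta_hat: Optional[float]
    gamma: Optional[float]
    mean_range_size: Optional[float]
    n_extant: int
    treeness: float


def _crown(tree: dendropy.Tree) -> dendropy.Node:
    """First node with >= 2 children (skips any stem chain)."""
    node = tree.seed_node
    while len(node.child_nodes()) == 1:
        node = node.child_nodes()[0]
    return node


def _node_depths(crown: dendropy.Node) -> Tuple[List[float], List[float]]:
    """(internal node depths, tip depths) measured from the crown."""
    internal, tips = [], []
    stack = [(crown, 0.0)]
    while stack:
        node, depth = stack.pop()
        kids = node.child_nodes()
        if kids:
            internal.append(depth)
            for child in kids:
                stack.append((child, depth + (child.edge.length or 0.0)))
        else:
            tips.append(depth)
    return internal, tips


def gamma_statistic(tree: dendropy.Tree) -> float:
    """Pybus–Harvey γ of an ultrametric extant-only timetree.

    With g_k the duration during which the reconstructed tree has k
    lineages (k = 2..n) and T_i = sum_{k=2..i} k g_k,

        γ = [ (1/(n−2)) Σ_{i=2}^{n−1} T_i − T_n/2 ] / ( T_n sqrt(1/(12(n−2))) )

    Negative values mean node depths cluster near the root, positive
    near the present; pure-birth trees have expectation 0.
    """
    crown = _crown(tree)
    internal, tips = _node_depths(crown)
    n = len(tips)
    if n < 3:
        raise ValueError(f"gamma requires >= 3 tips, got {n}")
    height = max(tips)
    if height <= 0:
        raise ValueError("tree has zero height")
    if max(tips) - min(tips) > 1e-6 * height:
        raise ValueError("tree is not ultrametric within tolerance")
    depths = sorted(internal)  # depths[0] == 0.0 is the crown split
    # g[k] = duration with k lineages; k runs 2..n
    g = [0.0] * (n + 1)
    for k in range(2, n):
        g[k] = depths[k - 1] - depths[k - 2]
    g[n] = height - depths[n - 2]
    T = [0.0] * (n + 1)
    for k in range(2, n + 1):
        T[k] = T[k - 1] + k * g[k]
    total = T[n]
    mean_partial = sum(T[i] for i in range(2, n)) / (n - 2)
    return (mean_partial - total / 2.0) / (total * math.sqrt(1.0 / (12.0 * (n - 2))))


def _clade_splits(tree: dendropy.Tree) -> List[Tuple[int, int]]:
    """(left, right) tip counts at each bifurcating internal node."""
    sizes: dict = {}
    splits = []
    for node in tree.postorder_node_iter():
        kids = node.child_nodes()
        if not kids:
            sizes[node] = 1
            continue
        if len(kids) != 2:
            raise ValueError(
                f"beta requires a binary tree; found a node with {len(kids)} children"
            )
        a, b = sizes[kids[0]], sizes[kids[1]]
        sizes[node] = a + b
        splits.append((a, b))
    return splits


def beta_loglik(beta: float, splits: List[Tuple[int, int]]) -> float:
    """Log-likelihood of clade-size splits under the beta-splitting model.

    For a clade of n tips the probability of an ordered split (i, n−i)
    is proportional to Γ(β+i+1)Γ(β+n−i+1) / (Γ(i+1)Γ(n−i+1)),
    normalized over i = 1..n−1.
    """
    ll = 0.0
    norms: dict = {}
    for a, b in splits:
        n = a + b
        if n not in norms:
            i = np.arange(1, n)
            terms = (
                gammaln(beta + i + 1)
                + gammaln(beta + n - i + 1)
                - gammaln(i + 1)
                - gammaln(n - i + 1)
            )
            norms[n] = terms.max() + math.log(np.exp(terms - terms.max()).sum())
        ll += (
            gammaln(beta + a + 1)
            + gammaln(beta + b + 1)
            - gammaln(a + 1)
            - gammaln(b + 1)
            - norms[n]
        )
    return ll


def beta_statistic(tree: dendropy.Tree) -> float:
    """Maximum-likelihood Aldous β on [−2, 10] from the tree topology.

    Bounded optimization with a coarse verification grid; estimates at
    the search boundary are returned as the bound itself.  Requires a
    binary tree with >= 4 tips (>= 2 informative splits).
    """
    splits = [s for s in _clade_splits(tree) if s[0] + s[1] >= 3]
    n_tips = sum(1 for _ in tree.leaf_node_iter())
    if n_tips < 4 or len(splits) < 2:
        raise ValueError("beta requires >= 4 tips and >= 2 informative splits")
    lo = BETA_LOWER + 1e-6
    res = minimize_scalar(
        lambda b: -beta_loglik(b, splits),
        bounds=(lo, BETA_UPPER),
        method="bounded",
        options={"xatol": 1e-6},
    )
    best_b, best_ll = float(res.x), -float(res.fun)
    # guard against local optima of the bounded search
    grid = np.linspace(lo, BETA_UPPER, 400)
    for b in grid:
        ll = beta_loglik(float(b), splits)
        if ll > best_ll + 1e-12 or (ll == best_ll and b < best_b):
            best_b, best_ll = float(b), ll
    if best_b <= BETA_LOWER + 1e-3:
        return BETA_LOWER
    if best_b >= BETA_UPPER - 1e-3:
        return BETA_UPPER
    return best_b


def mean_range_size(tip_states: pd.DataFrame) -> float:
    """Mean number of occupied regions per tip from a one-hot table.

    Expects one row per tip and one 0/1 presence column per region
    (any taxon-label column is ignored).
    """
    data = tip_states.select_dtypes(include=[np.number])
    sizes = data.to_numpy().sum(axis=1)
    if (sizes < 1).any():
        raise ValueError("every tip must occupy at least one region")
    return float(sizes.mean())


def treeness(tree: dendropy.Tree) -> float:
    """Proportion of total branch length in internal (non-pendant) edges."""
    internal = total = 0.0
    for edge in tree.preorder_edge_iter():
        if edge.length is None or edge.head_node is tree.seed_node:
            continue
        total += edge.length
        if edge.head_node.child_nodes():
            internal += edge.length
    return internal / total if total > 0 else 0.0


def summarize_tree(
    tree: dendropy.Tree, tip_states: Optional[pd.DataFrame] = None
) -> TreeStatSummary:
    """All tree statistics for one extant-only tree (None when undefined)."""
    n_tips = sum(1 for _ in tree.leaf_node_iter())
    try:
        gamma = gamma_statistic(tree)
    except ValueError:
        gamma = None
    try:
        beta = beta_statistic(tree)
    except ValueError:
        beta = None
    mrs = mean_range_size(tip_states) if tip_states is not None else None
    return TreeStatSummary(
        beta_hat=beta,
        gamma=gamma,
        mean_range_size=mrs,
        n_extant=n_tips,
        treeness=treeness(tree),
    )


@dataclass(frozen=True)
class GridDesign:
    """Mesh-grid simulation design over the three effect exponents.

    Evenly spaced points on each interval (endpoints included); the
    all-zero (diversity-independent) cell is excluded, and each
    remaining cell contributes ``reps`` accepted trees, i.e.
    ``(points_per_axis**3 - 1) * reps`` trees in total.  Trees are
    conditioned on surviving to ``tree_height`` with at least
    ``min_taxa`` extant tips (rejection sampling).
    """

    points_per_axis: int = 10
    reps: int = 50
    w_interval: Tuple[float, float] = (-2.0, 0.0)
    e_interval: Tuple[float, float] = (0.0, 2.0)
    d_interval: Tuple[float, float] = (-2.0, 0.0)
    tree_height: float = 100.0
    min_taxa: int = 3
    max_taxa: Optional[int] = None
    retry_budget: int = 500

    def __post_init__(self) -> None:
        if self.points_per_axis < 2:
            raise ValueError("points_per_axis must be >= 2")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")

    def axis(self, interval: Tuple[float, float]) -> np.ndarray:
        return np.linspace(interval[0], interval[1], self.points_per_axis)

    def cells(self) -> Iterator[Tuple[float, float, float]]:
        """(w_D, e_D, d_D_dest) triples, the all-zero cell excluded."""
        for w, e, d in product(
            self.axis(self.w_interval),
            self.axis(self.e_interval),
            self.axis(self.d_interval),
        ):
            if w == 0.0 and e == 0.0 and d == 0.0:
                continue
            yield float(w), float(e), float(d)


def grid_design_tree_count(design: GridDesign) -> int:
    """Total accepted trees a design requests, by cell enumeration."""
    return sum(design.reps for _ in design.cells())


# base event rates shared by all grid experiments
GRID_BASE_RATES = dict(rho_w=0.05, rho_d=0.05, rho_e=0.02, rho_b=0.02)


def run_grid_study(
    design: GridDesign,
    base: Optional[DDParams] = None,
    seed: int | None = None,
    n_regions: int = 3,
    root_range=frozenset({0}),
) -> pd.DataFrame:
    """Simulate the mesh-grid experiment and tabulate per-tree statistics.

    For every cell, accepted trees are extant-only trees that survived
    to ``design.tree_height`` with >= ``design.min_taxa`` tips.  Returns
    a long-format frame with one row per accepted tree (``accepted`` is
    False on rows of cells whose retry budget ran out; such cells are
    flagged, not fatal).
    """
    from .dataset import tip_state_table  # avoids a circular import

    rng = np.random.default_rng(seed)
    if base is None:
        base_kwargs = dict(GRID_BASE_RATES)
    else:
        base_kwargs = dict(
            rho_w=base.rho_w, rho_e=base.rho_e, rho_d=base.rho_d, rho_b=base.rho_b
        )
    rows = []
    stop = StopCondition(max_time=design.tree_height, max_taxa=design.max_taxa)
    for w, e, d in design.cells():
        params = DDParams(
            **base_kwargs,
            w_D=w,
            e_D=e,
            d_D_dest=d,
            d_D_src=0.0,
            b_D=0.0,
            n_regions=n_regions,
        )
        accepted = 0
        attempts = 0
        while accepted < design.reps and attempts < design.retry_budget:
            attempts += 1
            sim = simulate(params, stop, root_range=root_range, seed=rng)
            if sim.all_extinct or n_extant(sim) < design.min_taxa:
                continue
            pruned = prune_to_extant(sim)
            states = tip_state_table(sim)
            stats = summarize_tree(pruned, states)
            accepted += 1
            rows.append(
                dict(
                    w_D=w,
                    e_D=e,
                    d_D_dest=d,
                    rep=accepted,
                    n_extant=stats.n_extant,
                    mean_range_size=stats.mean_range_size,
                    gamma=stats.gamma,
                    beta_hat=stats.beta_hat,
                    treeness=stats.treeness,
                    accepted=True,
                )
            )
        if accepted < design.reps:
            rows.append(
                dict(
                    w_D=w,
                    e_D=e,
                    d_D_dest=d,
                    rep=accepted + 1,
                    n_extant=0,
                    mean_range_size=np.nan,
                    gamma=np.nan,
                    beta_hat=np.nan,
                    treeness=np.nan,
                    accepted=False,
                )
            )
    return pd.DataFrame(rows)
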