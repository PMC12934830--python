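"""Independent reference computations used to cross-check the package.

Everything here is written directly from first principles (standard
library math plus dendropy's own tree measures) and deliberately avoids
calling into the implementation it checks.
"""

from __future__ import annotations

import math
import random
from typing import List, Tuple

import dendropy
from dendropy.calculate import treemeasure


def gamma_reference(tree: dendropy.Tree) -> float:
    """Pybus-Harvey gamma via dendropy's independent implementation."""
    return treemeasure.pybus_harvey_gamma(tree)


def _splits(tree: dendropy.Tree) -> List[Tuple[int, int]]:
    sizes = {}
    out = []
    for node in tree.postorder_node_iter():
        kids = node.child_nodes()
        if not kids:
            sizes[node] = 1
        else:
            a, b = sizes[kids[0]], sizes[kids[1]]
            sizes[node] = a + b
            if a + b >= 3:
                out.append((a, b))
    return out


def beta_loglik_reference(beta: float, tree: dendropy.Tree) -> float:
    """Beta-splitting log-likelihood, coded independently with lgamma."""
    ll = 0.0
    for a, b in _splits(tree):
        n = a + b
        num = (
            math.lgamma(beta + a + 1)
            + math.lgamma(beta + b + 1)
            - math.lgamma(a + 1)
            - math.lgamma(b + 1)
        )
        z = math.log(
            sum(
                math.exp(
                    math.lgamma(beta + i + 1)
                    + math.lgamma(beta + n - i + 1)
                    - math.lgamma(i + 1)
                    - math.lgamma(n - i + 1)
                )
                for i in range(1, n)
            )
        )
        ll += num - z
    return ll


def beta_mle_grid(tree: dendropy.Tree, n_points: int = 1201) -> float:
    """Brute-force maximum of the beta-splitting likelihood on [-2, 10]."""
    lo, hi = -2.0 + 1e-6, 10.0
    best_b, best_ll = lo, -math.inf
    for k in range(n_points):
        b = lo + (hi - lo) * k / (n_points - 1)
        ll = beta_loglik_reference(b, tree)
        if ll > best_ll:
            best_b, best_ll = b, ll
    return best_b


def random_yule_tree(n_tips: int, seed: int) -> dendropy.Tree:
    """A pure-birth tree from dendropy's independent simulator.

    dendropy stops exactly at the n-th speciation event, leaving a
    zero-length final internode; a Yule tree observed at a random time
    conditional on n tips instead has a residual Exp(n * birth_rate)
    interval (memorylessness), so that residual is appended to every
    pendant edge to keep the internode-interval law correct.
    """
    from dendropy.simulate import treesim

    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    residual = rng.expovariate(n_tips * 1.0)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + residual
    return tree


def geosse_constant_rate_sim(
    rho_w: float,
    rho_e: float,
    rho_d: float,
    rho_b: float,
    max_time: float,
    rng: random.Random,
) -> int:
    """Minimal constant-rate 2-region GeoSSE; returns the extant count.

    Direct event-loop implementation with fixed rates: within-region
    speciation per occupied region, extinction per occupied region,
    dispersal to the unoccupied region, and (for two-region lineages) a
    single allopatric split at the base rate.
    """
    lineages = [frozenset({0})]
    t = 0.0
    while lineages:
        per_lineage = []
        for rng_set in lineages:
            size = len(rng_set)
            rate = size * (rho_w + rho_e)
            if size == 1:
                rate += rho_d
            else:
                rate += rho_b
            per_lineage.append(rate)
        total = sum(per_lineage)
        if total <= 0:
            break
        t += rng.expovariate(total)
        if t > max_time:
            break
        # pick lineage
        u = rng.random() * total
        acc = 0.0
        for idx, r in enumerate(per_lineage):
            acc += r
            if acc >= u:
                break
        target = lineages.pop(idx)
        size = len(target)
        # pick event within the lineage
        v = rng.random() * per_lineage[idx]
        if v < size * rho_w:
            region = sorted(target)[int(v // rho_w) % size]
            lineages.extend([target, frozenset({region})])
        elif v < size * (rho_w + rho_e):
            w = v - size * rho_w
            region = sorted(target)[int(w // rho_e) % size]
            reduced = target - {region}
            if reduced:
                lineages.append(reduced)
        elif size == 1:
            (occ,) = target
            lineages.append(frozenset({0, 1}))
        else:
            lineages.extend([frozenset({0}), frozenset({1})])
    return len(lineages)
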