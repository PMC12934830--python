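"""Training / validation dataset generation for likelihood-free inference.

Simulates extant-only Log-DDG trees under one of eight submodels
(switching diversity dependence on extinction, within-region
speciation, and inbound dispersal on or off), with base rates drawn
from a 50/50 mixture of uniform and log-uniform priors on [1e-4, 1] and
effect exponents drawn uniformly on (0, 2] (extinction) or [-2, 0)
(speciation / inbound dispersal) when active.  Each accepted replicate
is written as three plain-text files: a Newick tree (``<id>.tre``), a
one-hot tip-range table (``<id>.dat.csv``), and the true parameter
record (``<id>.labels.csv``).

Rejection sampling enforces the simulation conditions: a tree is
redrawn whenever it goes extinct or ends with fewer than 10 extant
taxa; the taxon cap (drawn uniformly from [100, 300]) and the stopping
time (drawn uniformly from [70, 100]) are per-replicate random
variables, so accepted trees vary in both height and size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import dendropy
import numpy as np
import pandas as pd

from .model import DDParams, SubmodelSpec
from .simulate import SimTree, StopCondition, n_extant, prune_to_extant, simulate, tip_label

__all__ = [
    "PriorSpec",
    "TrainingExample",
    "draw_parameters",
    "simulate_training_example",
    "make_training_set",
    "tip_state_table",
    "write_tip_states",
    "read_tip_states",
    "write_newick",
    "read_newick",
]


@dataclass(frozen=True)
class PriorSpec:
    """Priors and simulation conditions for training-set generation."""

    rate_interval: Tuple[float, float] = (1e-4, 1.0)
    e_D_interval: Tuple[float, float] = (1e-4, 2.0)
    w_D_interval: Tuple[float, float] = (-2.0, -1e-4)
    d_D_dest_interval: Tuple[float, float] = (-2.0, -1e-4)
    n_regions: int = 5
    min_taxa: int = 10
    max_taxa_interval: Tuple[float, float] = (100.0, 300.0)
    max_time_interval: Tuple[float, float] = (70.0, 100.0)


@dataclass
class TrainingExample:
    replicate: int
    tree: dendropy.Tree
    tip_states: pd.DataFrame
    labels: pd.Series
    params: DDParams
    max_taxa: int
    max_time: float


def _draw_rate(rng: np.random.Generator, interval: Tuple[float, float], log_uniform: bool) -> float:
    lo, hi = interval
    if log_uniform:
        return float(math.exp(rng.uniform(math.log(lo), math.log(hi))))
    return float(rng.uniform(lo, hi))


def draw_parameters(
    submodel: SubmodelSpec,
    prior: PriorSpec,
    rng: np.random.Generator,
    log_uniform_rates: bool = False,
) -> DDParams:
    """Draw one Log-DDG parameter set from the submodel's prior.

    Base rates come from the uniform or the log-uniform mixture
    component (chosen by the caller per replicate); inactive effect
    exponents are exactly 0, and outbound dispersal / between-region
    speciation are always diversity-independent.
    """
    rates = [
        _draw_rate(rng, prior.rate_interval, log_uniform_rates) for _ in range(4)
    ]
    e_D = float(rng.uniform(*prior.e_D_interval)) if submodel.dd_extinction else 0.0
    w_D = (
        float(rng.uniform(*prior.w_D_interval))
        if submodel.dd_within_speciation
        else 0.0
    )
    d_D_dest = (
        float(rng.uniform(*prior.d_D_dest_interval))
        if submodel.dd_dispersal_dest
        else 0.0
    )
    return DDParams(
        rho_w=rates[0],
        rho_e=rates[1],
        rho_d=rates[2],
        rho_b=rates[3],
        w_D=w_D,
        e_D=e_D,
        d_D_dest=d_D_dest,
        d_D_src=0.0,
        b_D=0.0,
        n_regions=prior.n_regions,
    )


def tip_state_table(sim: SimTree) -> pd.DataFrame:
    """One-hot presence/absence table for the extant tips of a simulation.

    One row per extant lineage (named like the Newick tip labels), one
    0/1 column per region.
    """
    rows = {}
    for ln in sim.extant:
        rows[tip_label(ln.id)] = [
            1 if i in ln.range_ else 0 for i in range(sim.n_regions)
        ]
    frame = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"region_{i}" for i in range(sim.n_regions)]
    )
    frame.index.name = "taxon"
    return frame


def simulate_training_example(
    submodel: SubmodelSpec,
    prior: PriorSpec,
    rng: np.random.Generator,
    replicate: int = 0,
    log_uniform_rates: Optional[bool] = None,
    retry_budget: int = 2000,
) -> TrainingExample:
    """Draw parameters and simulate until one replicate is accepted.

    Acceptance requires survival (no total extinction) and at least
    ``prior.min_taxa`` extant tips; the taxon cap and stop time are
    redrawn with the parameters on every attempt.  By default the
    mixture component alternates with the replicate index so any
    dataset size keeps the 50/50 uniform / log-uniform split.
    """
    if log_uniform_rates is None:
        log_uniform_rates = bool(replicate % 2)
    for attempt in range(retry_budget):
        params = draw_parameters(submodel, prior, rng, log_uniform_rates)
        max_taxa = int(round(rng.uniform(*prior.max_taxa_interval)))
        max_time = float(rng.uniform(*prior.max_time_interval))
        root_region = int(rng.integers(prior.n_regions))
        stop = StopCondition(max_time=max_time, max_taxa=max_taxa, min_taxa=prior.min_taxa)
        sim = simulate(params, stop, root_range=frozenset({root_region}), seed=rng)
        if sim.all_extinct or n_extant(sim) < prior.min_taxa:
            continue
        tree = prune_to_extant(sim)
        states = tip_state_table(sim)
        labels = pd.Series(
            dict(
                replicate=replicate,
                submodel=submodel.submodel_id,
                rho_w=params.rho_w,
                rho_e=params.rho_e,
                rho_d=params.rho_d,
                rho_b=params.rho_b,
                w_D=params.w_D,
                e_D=params.e_D,
                d_D_dest=params.d_D_dest,
                d_D_src=params.d_D_src,
                b_D=params.b_D,
                n_regions=params.n_regions,
                root_region=root_region,
                max_taxa=max_taxa,
                max_time=max_time,
                n_extant=n_extant(sim),
                log_uniform_rates=int(log_uniform_rates),
            )
        )
        return TrainingExample(
            replicate=replicate,
            tree=tree,
            tip_states=states,
            labels=labels,
            params=params,
            max_taxa=max_taxa,
            max_time=max_time,
        )
    raise RuntimeError(
        f"no accepted simulation for submodel {submodel.submodel_id} after "
        f"{retry_budget} attempts (last prior draw rejected)"
    )


def make_training_set(
    submodel: SubmodelSpec,
    n: int,
    outdir: str | Path,
    seed: int,
    prior: Optional[PriorSpec] = None,
) -> pd.DataFrame:
    """Generate ``n`` accepted replicates and write the three-file format.

    Files are ``<id>.tre`` (Newick), ``<id>.dat.csv`` (one-hot tip
    ranges) and ``<id>.labels.csv`` (true parameters) with zero-padded
    ids, plus a ``manifest.csv`` collecting all label rows.  Each
    replicate uses an independent child seed derived from ``seed``, so
    generation order (or parallel generation) cannot change results.
    """
    if prior is None:
        prior = PriorSpec()
    outdir = Path(outdir)
    if not outdir.is_dir():
        raise NotADirectoryError(f"output directory does not exist: {outdir}")
    width = max(4, len(str(max(n - 1, 0))))
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = seed_seq.spawn(n)
    records = []
    for rep in range(n):
        rng = np.random.default_rng(child_seeds[rep])
        example = simulate_training_example(submodel, prior, rng, replicate=rep)
        stem = f"{rep:0{width}d}"
        write_newick(example.tree, outdir / f"{stem}.tre")
        write_tip_states(example.tip_states, outdir / f"{stem}.dat.csv")
        example.labels.to_frame().T.to_csv(outdir / f"{stem}.labels.csv", index=False)
        records.append(example.labels)
    manifest = pd.DataFrame(records).reset_index(drop=True)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def write_tip_states(states: pd.DataFrame, path: str | Path) -> None:
    """Write a one-hot tip-range table as CSV (taxon column first)."""
    if (states.to_numpy().sum(axis=1) < 1).any():
        raise ValueError("refusing to write a tip with an empty range")
    states.to_csv(path, index=True)


def read_tip_states(path: str | Path) -> pd.DataFrame:
    """Read a one-hot tip-range CSV, validating that no range is empty."""
    frame = pd.read_csv(path, index_col=0)
    values = frame.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError(f"{path}: tip states must be 0/1")
    if (values.sum(axis=1) < 1).any():
        bad = frame.index[values.sum(axis=1) < 1].tolist()
        raise ValueError(f"{path}: tips with empty ranges: {bad}")
    return frame


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write a Newick string with branch lengths."""
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".9f",
    )


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree with branch lengths."""
    return dendropy.Tree.get(path=str(path), schema="newick")
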