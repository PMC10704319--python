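"""Kit-diffusion simulation on the bipartite index-alter network.

The observed secondary-distribution process is summarised as a simple
diffusion model: self-testing kits travel along the empirical edges (an edge
joins an index to an alter who redeemed a kit with that index's confirmation
code).  Each seeded index starts with a fixed kit allocation (default 4) and,
at every time step, each kit-holding distributor draws the number of kits it
wants to pass on from a Poisson distribution whose mean equals the number of
kits it received; the draw is capped by kits actually held and by unreached
neighbours (the raw Poisson is uncapped, but kit conservation demands caps).
Receiving a kit marks a node as tested — the efficiency metric equates
receiving with self-testing.

Intervention efficiency is the percentage of network nodes (indexes plus
alters) tested when the process goes quiet or the step guard is hit; it is
the quantity compared between ML-identified and scale-identified seed sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from peerselect.errors import IntegrityError
from peerselect.synthetic import TrialDataset
from peerselect.evaluate import fold_diff_ci


class SimulationConfig(BaseModel):
    """Diffusion-model parameters."""

    kits_per_seed: int = Field(default=4, ge=1)
    max_steps: int = Field(default=10, ge=1)
    redistribution: bool = False
    rng_seed: int = 0


def build_network(indexes: pd.DataFrame, alters: pd.DataFrame) -> nx.Graph:
    """Bipartite distribution network: one node per index and per alter, one
    edge per alter row (alter -> the index whose code it redeemed)."""
    known = set(indexes["index_id"])
    dangling = set(alters["index_id"]) - known if len(alters) else set()
    if dangling:
        raise IntegrityError(f"alters reference unknown index id(s): {sorted(dangling)[:5]}")
    g = nx.Graph()
    g.add_nodes_from(indexes["index_id"], bipartite="index")
    if len(alters):
        g.add_nodes_from(alters["alter_id"], bipartite="alter")
        g.add_edges_from(zip(alters["index_id"], alters["alter_id"]))
    return g


@dataclass
class SimulationResult:
    """Outcome of one simulation run."""

    tested: set
    transfers: list[tuple[int, str, str]]  # (step, from, to)
    n_nodes: int
    kits_injected: int

    @property
    def efficiency(self) -> float:
        if self.n_nodes == 0:
            raise ValueError("empty network has no efficiency")
        return 100.0 * len(self.tested) / self.n_nodes


def simulate(
    network: nx.Graph, seeds: Iterable[str], config: SimulationConfig | None = None
) -> SimulationResult:
    """Run the Poisson kit-diffusion process to quiescence (or ``max_steps``).

    Seeds start holding ``kits_per_seed`` kits with Poisson mean
    ``kits_per_seed`` and are marked tested.  Per step, every eligible
    kit-holder draws d ~ Poisson(mean), capped at kits held and at unreached
    neighbours, and passes one kit each to that many distinct unreached
    neighbours chosen uniformly without replacement; receivers are marked
    tested and take the received count as their own Poisson mean.  With
    ``redistribution`` false only index nodes distribute.  Deterministic
    given ``rng_seed``.
    """
    config = config or SimulationConfig()
    seeds = sorted(set(seeds))
    unknown = [s for s in seeds if s not in network]
    if unknown:
        raise ValueError(f"unknown seed id(s): {unknown[:5]}")
    rng = np.random.default_rng(config.rng_seed)

    kits = {node: 0 for node in network.nodes}
    lam = {node: 0.0 for node in network.nodes}
    tested: set = set()
    for s in seeds:
        kits[s] = config.kits_per_seed
        lam[s] = float(config.kits_per_seed)
        tested.add(s)

    is_index = {n: network.nodes[n].get("bipartite") == "index" for n in network.nodes}
    transfers: list[tuple[int, str, str]] = []
    for step in range(1, config.max_steps + 1):
        moved = False
        received_now: dict[str, int] = {}
        # iterate in sorted order so the run is reproducible
        for node in sorted(kits):
            if kits[node] <= 0 or lam[node] <= 0:
                continue
            if not config.redistribution and not is_index[node]:
                continue
            unreached = sorted(nbr for nbr in network.neighbors(node) if nbr not in tested)
            if not unreached:
                continue
            d = int(rng.poisson(lam[node]))
            d = min(d, kits[node], len(unreached))
            if d <= 0:
                continue
            chosen = rng.choice(len(unreached), size=d, replace=False)
            for j in sorted(int(c) for c in chosen):
                receiver = unreached[j]
                kits[node] -= 1
                kits[receiver] += 1
                tested.add(receiver)
                received_now[receiver] = received_now.get(receiver, 0) + 1
                transfers.append((step, node, receiver))
                moved = True
        for node, got in received_now.items():
            lam[node] = float(got)
        if not moved:
            break
    return SimulationResult(
        tested=tested,
        transfers=transfers,
        n_nodes=network.number_of_nodes(),
        kits_injected=len(seeds) * config.kits_per_seed,
    )


def intervention_efficiency(result: SimulationResult) -> float:
    """Percentage of network nodes tested at the end of the run, one decimal."""
    return round(result.efficiency, 1)


@dataclass
class StrategyComparison:
    """Per-fold intervention efficiencies of two seeding strategies."""

    ml_per_fold: list[float]
    baseline_per_fold: list[float]
    ml_average: float
    baseline_average: float
    diff_mean: float
    diff_ci: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "ml_per_fold": self.ml_per_fold,
            "baseline_per_fold": self.baseline_per_fold,
            "ml_average": self.ml_average,
            "baseline_average": self.baseline_average,
            "difference": self.diff_mean,
            "difference_ci95": list(self.diff_ci),
        }


def _fold_efficiency(
    indexes: pd.DataFrame,
    alters: pd.DataFrame,
    seeds: Sequence[str],
    config: SimulationConfig,
    n_replicates: int,
    rep_seeds: Sequence[int],
) -> float:
    network = build_network(indexes, alters)
    if network.number_of_nodes() == 0:
        raise ValueError("empty fold network")
    effs = []
    for r in range(n_replicates):
        cfg = config.model_copy(update={"rng_seed": int(rep_seeds[r])})
        effs.append(simulate(network, seeds, cfg).efficiency)
    return float(np.mean(effs))


def compare_strategies(
    dataset: TrialDataset,
    folds: Sequence[np.ndarray],
    ml_flags: Sequence[int],
    baseline_flags: Sequence[int],
    config: SimulationConfig | None = None,
    n_replicates: int = 20,
) -> StrategyComparison:
    """Compare intervention efficiency of ML-flagged vs scale-flagged seeds.

    For each cross-validation test fold, the fold's own index-alter network
    is built and each strategy seeds its flagged indexes within the fold.
    Efficiencies average over ``n_replicates`` simulation repeats using
    common random numbers across strategies (the same replicate seeds), so
    identical flag sets yield exactly identical efficiencies.
    """
    config = config or SimulationConfig()
    ml_flags = np.asarray(ml_flags, dtype=int)
    baseline_flags = np.asarray(baseline_flags, dtype=int)
    ids = dataset.indexes["index_id"].to_numpy()
    ml_eff, base_eff = [], []
    ss = np.random.SeedSequence(config.rng_seed)
    for fold_i, test_idx in enumerate(folds):
        fold_ids = ids[test_idx]
        idx_rows = dataset.indexes[dataset.indexes["index_id"].isin(fold_ids)]
        alt_rows = dataset.alters[dataset.alters["index_id"].isin(fold_ids)]
        rep_seeds = ss.spawn(1)[0].generate_state(n_replicates) >> 1  # keep < 2**31
        ml_seeds = ids[test_idx[ml_flags[test_idx] == 1]]
        base_seeds = ids[test_idx[baseline_flags[test_idx] == 1]]
        ml_eff.append(
            _fold_efficiency(idx_rows, alt_rows, ml_seeds, config, n_replicates, rep_seeds)
        )
        base_eff.append(
            _fold_efficiency(idx_rows, alt_rows, base_seeds, config, n_replicates, rep_seeds)
        )
    diffs = [m - b for m, b in zip(ml_eff, base_eff)]
    mean, lo, hi = fold_diff_ci(diffs)
    return StrategyComparison(
        ml_per_fold=[round(e, 1) for e in ml_eff],
        baseline_per_fold=[round(e, 1) for e in base_eff],
        ml_average=round(float(np.mean(ml_eff)), 1),
        baseline_average=round(float(np.mean(base_eff)), 1),
        diff_mean=mean,
        diff_ci=(lo, hi),
    )
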