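"""The per-tick schedule of one simulation run.

Each tick applies, in order: (1) resource degradation on every patch, with
Moore diffusion on replenishment ticks; (2) recomputation of each living
cell's link count, exposed surface and vulnerability from the current
contact network; (3) the threat cost on every living cell; (4) a
simultaneous death check — cells whose energy budget is exhausted die, and,
from the post-energy-death snapshot, cells left without any living
neighbour within the anoikis radius die of anoikis; (5) survivors harvest
energy from their patch.  Cells never move, divide or form new links, so
the contact network only loses nodes over time and cluster fragmentation
is driven purely by cell death.

A run ends when all cells are dead, when no death has occurred for
``steady_window`` consecutive ticks (steady state — the end states the
outcome metrics summarise), or at the ``max_ticks`` hard stop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import networkx as nx
import numpy as np

from . import core
from .initialize import (
    ClusterLayout,
    PatchGrid,
    build_contact_network,
    generate_cluster,
    init_environment,
    pairwise_adjacency,
)
from .params import ModelParams

#: Death causes recorded in the death log.
CAUSE_ENERGY = "energy"
CAUSE_ANOIKIS = "anoikis"


@dataclass(eq=False)
class WorldState:
    """Mutable state of one simulation between ticks."""

    tick: int
    positions: np.ndarray            # (n, 2) fixed cell coordinates
    energy: np.ndarray               # (n,) energy budgets
    metabolic: np.ndarray            # (n,) invariant metabolic rates
    alive: np.ndarray                # (n,) bool
    link_adj: np.ndarray             # (n, n) bool, distance <= link_radius
    anoikis_adj: np.ndarray          # (n, n) bool, distance <= anoikis_radius
    patch_ix: np.ndarray             # (n,) int, patch row of each cell
    patch_iy: np.ndarray             # (n,) int, patch column of each cell
    patches: PatchGrid
    rng: np.random.Generator
    death_log: List[Tuple[int, int, str]] = field(default_factory=list)
    last_death_tick: int = 0

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    def living_degrees(self) -> np.ndarray:
        """Number of living linked neighbours for every cell."""
        # bool @ bool would collapse to any(); count in integers
        return self.link_adj @ self.alive.astype(np.int64)

    def network(self) -> nx.Graph:
        """Contact graph restricted to living cells (nodes keep their ids)."""
        graph = nx.Graph()
        idx = np.nonzero(self.alive)[0]
        for i in idx:
            graph.add_node(int(i), x=float(self.positions[i, 0]),
                           y=float(self.positions[i, 1]))
        sub = self.link_adj & self.alive[:, None] & self.alive[None, :]
        graph.add_edges_from(
            (int(i), int(j)) for i, j in zip(*np.nonzero(np.triu(sub)))
        )
        return graph


@dataclass(eq=False)
class RunResult:
    """End-state record of one run (one row of a sweep table)."""

    n_initial: int
    n_final: int
    components_final: int
    end_tick: int
    end_reason: str                  # all_dead | steady_state | max_ticks
    median_energy: float             # over living cells; NaN when all dead
    median_resource: float           # over all patches at the end
    median_metabolic: float          # over living cells; NaN when all dead
    params: ModelParams
    seed: int
    death_log: List[Tuple[int, int, str]]
    edges: List[Tuple[int, int]]     # final living-cell contact edges
    positions: np.ndarray
    alive: np.ndarray
    layout: ClusterLayout
    trace: Optional[List[Tuple[int, int, float, float]]] = None

    def to_row(self) -> dict:
        """Flat summary used by the sweep table."""
        return {
            "density": self.params.density_class,
            "n_cells": self.n_initial,
            "threat": self.params.threat_level,
            "resource": self.params.resource_level,
            "seed": self.seed,
            "n_final": self.n_final,
            "components": self.components_final,
            "end_tick": self.end_tick,
            "end_reason": self.end_reason,
            "median_energy": self.median_energy,
            "median_resource": self.median_resource,
        }


def make_world(params: ModelParams,
               rng: Optional[np.random.Generator] = None) -> WorldState:
    """Initialise environment, cluster and contact network for one run."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    layout = generate_cluster(params, rng)
    patches = init_environment(params)
    dims = (float(params.grid_width), float(params.grid_height))
    link_adj = pairwise_adjacency(layout.positions, params.link_radius, dims)
    if params.anoikis_radius == params.link_radius:
        anoikis_adj = link_adj
    else:
        anoikis_adj = pairwise_adjacency(
            layout.positions, params.anoikis_radius, dims
        )
    n = params.n_cells
    world = WorldState(
        tick=0,
        positions=layout.positions,
        energy=np.full(n, float(params.initial_energy)),
        metabolic=np.full(n, float(params.metabolic)),
        alive=np.ones(n, dtype=bool),
        link_adj=link_adj,
        anoikis_adj=anoikis_adj,
        patch_ix=np.floor(layout.positions[:, 0]).astype(int) % params.grid_width,
        patch_iy=np.floor(layout.positions[:, 1]).astype(int) % params.grid_height,
        patches=patches,
        rng=rng,
    )
    world._layout = layout  # kept for the run record
    return world


def step(world: WorldState, params: ModelParams) -> WorldState:
    """Advance the world by one tick (mutates and returns ``world``)."""
    # (1) patch dynamics: degradation every tick, diffusion periodically
    diffusion_active = world.tick % params.replenish_period == 0
    world.patches.resource = core.step_resource_grid(
        world.patches.resource, params.d, params.k,
        diffusion_active, params.diffusion_mode,
    )

    alive = world.alive
    # (2) refresh derived cell properties from the current living network
    degrees = world.living_degrees()
    surface = core.compute_surface(degrees)
    vulnerability = core.compute_vulnerability(surface, params.a, params.b)

    threat_here = world.patches.threat[world.patch_ix, world.patch_iy]
    resource_here = world.patches.resource[world.patch_ix, world.patch_iy]
    cost = core.energy_cost(threat_here, vulnerability)
    gain = core.energy_gain(resource_here, world.metabolic, surface)

    # (3) threat cost (optionally the single combined budget update)
    if params.combined_energy_update:
        world.energy[alive] += gain[alive] - cost[alive]
    else:
        world.energy[alive] -= cost[alive]

    # (4) simultaneous death check: energy first, then anoikis on the
    # post-energy-death snapshot.  Cascades propagate on later ticks.
    energy_dead = alive & (world.energy <= 0.0)
    still_alive = alive & ~energy_dead
    living_support = world.anoikis_adj @ still_alive.astype(np.int64)
    isolated = still_alive & (living_support == 0)
    if params.anoikis_prob < 1.0 and isolated.any():
        roll = world.rng.random(isolated.size)
        isolated &= roll < params.anoikis_prob
    for i in np.nonzero(energy_dead)[0]:
        world.death_log.append((world.tick, int(i), CAUSE_ENERGY))
    for i in np.nonzero(isolated)[0]:
        world.death_log.append((world.tick, int(i), CAUSE_ANOIKIS))
    world.alive = still_alive & ~isolated

    # (5) survivors harvest energy (skipped in combined mode, already added)
    if not params.combined_energy_update:
        survivors = world.alive
        world.energy[survivors] += gain[survivors]

    if energy_dead.any() or isolated.any():
        world.last_death_tick = world.tick + 1
    world.tick += 1
    return world


def run(params: ModelParams, record_trace: bool = False) -> RunResult:
    """Run one simulation to termination; deterministic given the seed."""
    world = make_world(params)
    trace: Optional[list] = [] if record_trace else None
    end_reason = "max_ticks"
    while True:
        if world.n_alive == 0:
            end_reason = "all_dead"
            break
        if world.tick - world.last_death_tick >= params.steady_window:
            end_reason = "steady_state"
            break
        if world.tick >= params.max_ticks:
            end_reason = "max_ticks"
            break
        step(world, params)
        if trace is not None:
            living = world.energy[world.alive]
            trace.append((
                world.tick,
                world.n_alive,
                world.patches.total_resource(),
                float(np.median(living)) if living.size else float("nan"),
            ))
    return _finalize(world, params, end_reason, trace)


def _finalize(world: WorldState, params: ModelParams, end_reason: str,
              trace: Optional[list]) -> RunResult:
    from .metrics import count_components  # local import avoids a cycle

    network = world.network()
    n_final = world.n_alive
    living_energy = world.energy[world.alive]
    living_metabolic = world.metabolic[world.alive]
    return RunResult(
        n_initial=len(world.alive),
        n_final=n_final,
        components_final=count_components(network),
        end_tick=world.tick,
        end_reason=end_reason,
        median_energy=float(np.median(living_energy)) if n_final else float("nan"),
        median_resource=float(np.median(world.patches.resource)),
        median_metabolic=float(np.median(living_metabolic)) if n_final else float("nan"),
        params=params,
        seed=params.seed,
        death_log=list(world.death_log),
        edges=sorted(tuple(sorted(e)) for e in network.edges()),
        positions=world.positions,
        alive=world.alive.copy(),
        layout=getattr(world, "_layout", None),
        trace=trace,
    )
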