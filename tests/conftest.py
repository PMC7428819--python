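"""Shared fixtures: fast parameter sets and hand-built worlds."""

import numpy as np
import pytest

from ctcsim import ModelParams
from ctcsim.initialize import PatchGrid
from ctcsim.simulate import WorldState


@pytest.fixture
def quick_params():
    """Small, fast run configuration (short horizon, tiny cluster)."""
    return ModelParams(n_cells=10, density_class="medium",
                      max_ticks=120, steady_window=30, seed=7)


def build_world(positions, params, energy=None):
    """WorldState over explicit positions (bypasses the layout sampler)."""
    from ctcsim.initialize import init_environment, pairwise_adjacency

    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    dims = (float(params.grid_width), float(params.grid_height))
    link_adj = pairwise_adjacency(positions, params.link_radius, dims)
    if params.anoikis_radius == params.link_radius:
        anoikis_adj = link_adj
    else:
        anoikis_adj = pairwise_adjacency(positions, params.anoikis_radius, dims)
    if energy is None:
        energy = np.full(n, float(params.initial_energy))
    return WorldState(
        tick=0,
        positions=positions,
        energy=np.asarray(energy, dtype=float),
        metabolic=np.full(n, float(params.metabolic)),
        alive=np.ones(n, dtype=bool),
        link_adj=link_adj,
        anoikis_adj=anoikis_adj,
        patch_ix=np.floor(positions[:, 0]).astype(int) % params.grid_width,
        patch_iy=np.floor(positions[:, 1]).astype(int) % params.grid_height,
        patches=init_environment(params),
        rng=np.random.default_rng(params.seed),
    )
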