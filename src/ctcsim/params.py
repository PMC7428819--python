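"""Model parameters and scenario-level mappings.

A single :class:`ModelParams` record carries every constant of the model:
the environment geometry (a toroidal patch grid), the energy-budget
constants of the cell agents, the resource degradation/diffusion constants
of the patch agents, and the scenario knobs (cluster size, density class,
threat and resource levels) that the experiment sweeps vary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

#: Area-per-cell (patch^2) used to size the overall layout disc for each
#: qualitative density class.  High-density clusters pack cells so tightly
#: that the contact graph is nearly a clique under a 1-patch link radius;
#: low-density clusters are sparse, branched networks spread over a much
#: larger footprint.
DENSITY_AREA = {"high": 0.45, "medium": 2.0, "low": 3.0}

#: Minimum initial contact degree per density class.  Layouts violating it
#: are redrawn: "high density" means tightly packed clusters in which every
#: cell touches several neighbours, not merely a small disc that happens to
#: contain a dangling cell.
DENSITY_MIN_DEGREE = {"high": 4, "medium": 1, "low": 1}

#: Minimum centre-to-centre placement spacing (patch units) inside a lobe.
#: The physical non-overlap floor is the cell extent (0.5); looser classes
#: keep cells farther apart, which is what makes their contact networks
#: sparse and branched rather than clique-like.
DENSITY_SPACING = {"high": 0.5, "medium": 0.55, "low": 0.68}

#: Lobe-count coefficient per density class: a cluster of N cells is grown
#: as roughly ``coef * sqrt(N)`` dense lobes joined by single-cell-wide
#: bridges.  High-density clusters are a single compact blob (coef 0);
#: looser clusters are the "loosely connected or branched" morphologies
#: seen in patient-derived clusters.
DENSITY_LOBE_COEF = {"high": 0.0, "medium": 0.31, "low": 0.45}

#: Area-per-cell (patch^2) of the disc each individual lobe is grown in.
DENSITY_LOBE_AREA = {"high": 0.45, "medium": 0.38, "low": 0.70}

#: Open bridge length (patch units) between the rims of adjacent lobes;
#: the cells laid across this gap are pure degree-2 bridge cells.
SEED_CHAIN_GAP = {"medium": 2.2, "low": 3.0}

#: Elongation of single-blob (high-density) layouts: each layout draws an
#: axis ratio uniformly in [base + lo_slope * n, base + hi_slope * n]
#: (capped at max), spanning spherical to linear-leaning cluster shapes;
#: larger clusters tend to be the more irregular, elongated ones.
BLOB_ASPECT = {"base": 1.0, "lo_slope": 0.020, "hi_slope": 0.032, "max": 4.5}

#: Cohesive-core (kernel) rate for high-density blobs: a cluster of N
#: cells is grown around ``max(2, round(rate * N))`` kernels of 6 mutually
#: linked cells (a regular hexagon of circumradius 0.5).  Kernel cells
#: keep at least 5 contacts for life, modelling the tightly adherent cores
#: (desmosome-rich cell groups) that make dense clusters hard to
#: eradicate.
KERNEL_RATE_HIGH = 0.05

#: Centre-to-centre step (patch units) between consecutive cells of a
#: bridge chain: within the link radius (bridges hold the cluster
#: together) but beyond the anoikis support radius (bridge cells lack the
#: close contact that suppresses anoikis, which is what makes bridges the
#: cluster's breaking points).
CHAIN_SPACING = 0.92

#: Maximum nearest-neighbour distance enforced during lobe/blob growth, so
#: that every cell of a dense region starts with contact support inside
#: the anoikis radius.
SUPPORT_RADIUS = 0.85

#: Qualitative resource-level mapping (arbitrary resource units per patch).
RESOURCE_LEVELS = {
    "very_low": 0.2,
    "low": 0.4,
    "medium": 0.6,
    "high": 0.8,
    "very_high": 1.0,
}

#: Qualitative threat-level mapping.  The threat sweep uses the numeric grid
#: 0.1-0.8 directly; "very_low" is the background threat of an otherwise
#: optimal environment.
THREAT_LEVELS = {"very_low": 0.05}

_VALID_DENSITIES = frozenset(DENSITY_AREA)
_VALID_DIFFUSION = frozenset({"conserving", "literal"})


class ConfigError(ValueError):
    """Raised when a parameter set violates a model invariant."""


@dataclass
class ModelParams:
    """All constants and scenario knobs of one simulation.

    Defaults are the package's calibrated reference parameterisation; every
    field can be overridden per run or via a TOML config file.
    """

    # --- environment geometry -------------------------------------------
    grid_width: int = 33
    grid_height: int = 33
    cell_extent: float = 0.5  # cell edge length, patch units

    # --- vulnerability sigmoid ------------------------------------------
    a: float = 3.38
    b: float = 10.66

    # --- resource dynamics ----------------------------------------------
    d: float = 0.05            # per-tick degradation fraction
    k: Optional[float] = None   # per-diffusion-event diffusion fraction;
    # None picks the value balancing degradation over one replenish cycle
    replenish_period: int = 10  # ticks between diffusion events
    diffusion_mode: str = "literal"

    # --- cell energetics -------------------------------------------------
    metabolic: float = 0.04    # resource -> energy conversion factor
    initial_energy: float = 0.2

    # --- contact / anoikis geometry --------------------------------------
    link_radius: float = 1.0
    anoikis_radius: Optional[float] = 0.9  # None: use link_radius
    anoikis_prob: float = 1.0

    # --- scenario ---------------------------------------------------------
    threat_level: float = THREAT_LEVELS["very_low"]
    resource_level: float = RESOURCE_LEVELS["very_high"]
    n_cells: int = 20
    density_class: str = "high"

    # --- scheduling -------------------------------------------------------
    max_ticks: int = 200
    steady_window: int = 110   # deathless ticks declaring steady state
    combined_energy_update: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_width <= 0 or self.grid_height <= 0:
            raise ConfigError("grid dimensions must be positive")
        if not (0.0 <= self.d < 1.0):
            raise ConfigError(f"degradation fraction d={self.d} outside [0, 1)")
        if self.k is None:
            from .core import balanced_diffusion_k  # deferred: avoid cycle
            self.k = balanced_diffusion_k(self.d, self.replenish_period)
        if not (0.0 <= self.k < 1.0):
            raise ConfigError(f"diffusion fraction k={self.k} outside [0, 1)")
        if self.replenish_period < 1:
            raise ConfigError("replenish_period must be a positive integer")
        if self.metabolic <= 0:
            raise ConfigError("metabolic rate must be > 0")
        if self.initial_energy <= 0:
            raise ConfigError("initial_energy must be > 0")
        if self.link_radius <= 0:
            raise ConfigError("link_radius must be > 0")
        if self.anoikis_radius is None:
            self.anoikis_radius = self.link_radius
        if self.anoikis_radius <= 0:
            raise ConfigError("anoikis_radius must be > 0")
        if not (0.0 <= self.anoikis_prob <= 1.0):
            raise ConfigError("anoikis_prob must lie in [0, 1]")
        if self.threat_level < 0:
            raise ConfigError("threat_level must be >= 0")
        if self.resource_level < 0:
            raise ConfigError("resource_level must be >= 0")
        if self.n_cells < 2:
            raise ConfigError("n_cells must be >= 2 (a cluster, not a cell)")
        if self.density_class not in _VALID_DENSITIES:
            raise ConfigError(
                f"density_class {self.density_class!r} not in {sorted(_VALID_DENSITIES)}"
            )
        if self.diffusion_mode not in _VALID_DIFFUSION:
            raise ConfigError(
                f"diffusion_mode {self.diffusion_mode!r} not in {sorted(_VALID_DIFFUSION)}"
            )
        if self.max_ticks < 1 or self.steady_window < 1:
            raise ConfigError("max_ticks and steady_window must be positive")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    @property
    def density_area(self) -> float:
        """Area per cell (patch^2) implied by the density class."""
        return DENSITY_AREA[self.density_class]
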