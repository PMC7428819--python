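"""The model's update rules as pure, individually testable functions.

Cells are energy-budget agents.  A cell's exposed *surface* shrinks
hyperbolically with the number of physical links it keeps to neighbouring
cells; its *vulnerability* to extrinsic threats (drugs, immune attack) is a
steep sigmoid of that surface, so well-connected interior cells are almost
shielded while poorly connected peripheral cells are nearly fully exposed.
Each tick a cell pays an energy cost proportional to the local patch threat
times its vulnerability and, if it survives, harvests energy from the local
patch resource in proportion to its metabolic rate and exposed surface.

Patches carry a resource field that degrades by a fixed fraction per tick
and is redistributed by Moore-neighbourhood diffusion at regular intervals.
"""

from __future__ import annotations

import numpy as np

#: Clamp for the sigmoid exponent argument, guarding against overflow.
EXP_CLAMP = 500.0


def _as_array(x):
    arr = np.asarray(x, dtype=float)
    return arr, arr.ndim == 0


def compute_surface(n_links):
    """Exposed surface fraction of a cell with ``n_links`` contacts.

    An isolated cell exposes its whole surface (1.0); every additional
    link to a neighbour shields a share of it: ``surface = 1 / (n_links + 1)``.

    Accepts scalars or arrays; raises ``ValueError`` on negative counts.
    """
    arr, scalar = _as_array(n_links)
    if np.any(arr < 0):
        raise ValueError("n_links must be non-negative")
    out = 1.0 / (arr + 1.0)
    return float(out) if scalar else out


def compute_vulnerability(surface, a: float, b: float):
    """Sigmoid susceptibility to threat as a function of exposed surface.

    ``vulnerability = 1 / (1 + exp(-((surface * a - 1) * b)))``

    ``a`` positions the midpoint (vulnerability is exactly 0.5 where
    ``surface * a == 1``, i.e. at ``a - 1`` links) and ``b`` sets the
    steepness.  The exponent argument is clamped to ±500 to avoid overflow.
    """
    arr, scalar = _as_array(surface)
    z = np.clip((arr * a - 1.0) * b, -EXP_CLAMP, EXP_CLAMP)
    out = 1.0 / (1.0 + np.exp(-z))
    return float(out) if scalar else out


def energy_gain(resource, metabolic, surface):
    """Energy harvested in one tick: ``resource * metabolic * surface``."""
    out = np.asarray(resource, dtype=float) * metabolic * surface
    return float(out) if out.ndim == 0 else out


def energy_cost(threat, vulnerability):
    """Energy drained by the local threat: ``threat * vulnerability``."""
    out = np.asarray(threat, dtype=float) * vulnerability
    return float(out) if out.ndim == 0 else out


def _check_fractions(d: float, k: float) -> None:
    if not (0.0 <= d < 1.0):
        raise ValueError(f"degradation fraction d={d} outside [0, 1)")
    if not (0.0 <= k < 1.0):
        raise ValueError(f"diffusion fraction k={k} outside [0, 1)")


def update_patch_resource(
    own: float,
    neighbor_resources,
    d: float,
    k: float,
    diffusion_active: bool,
    mode: str = "conserving",
) -> float:
    """One-patch resource update (scalar reference implementation).

    Without diffusion the patch simply degrades: ``own * (1 - d)``.  On a
    diffusion tick the default ``conserving`` mode lets the patch export a
    fraction ``k`` of its stock, split equally among its 8 Moore neighbours,
    while importing the matching share of theirs, then degrades::

        (own * (1 - k) + (k / 8) * sum(neighbours)) * (1 - d)

    With ``d = 0`` this conserves the grid total exactly and leaves uniform
    fields untouched.  ``mode="literal"`` instead adds a fraction ``k`` of
    the neighbours' total with no matching outflow
    (``own * (1 - d) + k * sum(neighbours)``), which injects resource; it is
    kept for sensitivity comparisons only.
    """
    _check_fractions(d, k)
    nbrs = np.asarray(neighbor_resources, dtype=float)
    if not diffusion_active:
        return float(own * (1.0 - d))
    if mode == "conserving":
        return float((own * (1.0 - k) + (k / 8.0) * nbrs.sum()) * (1.0 - d))
    if mode == "literal":
        return float(own * (1.0 - d) + k * nbrs.sum())
    raise ValueError(f"unknown diffusion mode {mode!r}")


def balanced_diffusion_k(d: float, replenish_period: int) -> float:
    """Diffusion fraction that balances degradation over one cycle.

    Under the resource-injecting ("literal") diffusion rule, a uniform
    field is multiplied by ``(1 - d) + 8k`` on a diffusion tick and by
    ``(1 - d)`` on each of the other ``replenish_period - 1`` ticks of a
    cycle.  Choosing ::

        k = (1 - (1 - d)**P) / (8 * (1 - d)**(P - 1))

    makes the cycle factor exactly 1: periodic diffusive delivery replaces
    what degradation removed, so the mean resource level is stationary (a
    within-cycle sawtooth around the scenario's resource level) instead of
    decaying to zero — an environment that keeps being perfused, as a
    capillary bed does.
    """
    _check_fractions(d, 0.0)
    p = int(replenish_period)
    if p < 1:
        raise ValueError("replenish_period must be a positive integer")
    return (1.0 - (1.0 - d) ** p) / (8.0 * (1.0 - d) ** (p - 1))


#: Moore-neighbourhood shifts (8 surrounding patches).
_MOORE = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]


def moore_neighbor_sum(field: np.ndarray) -> np.ndarray:
    """Sum of the 8 Moore neighbours of every patch, with toroidal wrap."""
    total = np.zeros_like(field)
    for di, dj in _MOORE:
        total += np.roll(field, (di, dj), axis=(0, 1))
    return total


def step_resource_grid(
    resource: np.ndarray,
    d: float,
    k: float,
    diffusion_active: bool,
    mode: str = "conserving",
) -> np.ndarray:
    """Vectorised whole-grid version of :func:`update_patch_resource`."""
    _check_fractions(d, k)
    if not diffusion_active:
        return resource * (1.0 - d)
    nbr = moore_neighbor_sum(resource)
    if mode == "conserving":
        return (resource * (1.0 - k) + (k / 8.0) * nbr) * (1.0 - d)
    if mode == "literal":
        return resource * (1.0 - d) + k * nbr
    raise ValueError(f"unknown diffusion mode {mode!r}")
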