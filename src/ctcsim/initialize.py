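"""Environment and cluster initialization.

The environment is a toroidal grid of patches with homogeneous resource and
threat fields set by the scenario.  Cluster layouts are random geometric
arrangements centred on the grid, drawn by sequential adjacency-constrained
dart-throwing (a new cell must respect the non-overlap separation and land
in contact with the growing cluster, so every layout's contact graph is
connected by construction; a cluster that starts fragmented would confound
initialization artefacts with the fragmentation the model studies).

High-density clusters are single compact blobs — spherical to elongated —
in which every cell starts with several contacts and a few 6-cell cohesive
kernels (mutually linked pentagon-plus-centre motifs) model tightly
adherent cell cores.  Medium- and low-density clusters are grown as dense
lobes joined by single-cell-wide bridge chains: the loosely connected,
branched morphologies of patient-derived clusters.  Bridge cells are
linked but spaced beyond the anoikis support radius, which makes bridges
the cluster's natural breaking points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .params import (
    BLOB_ASPECT,
    CHAIN_SPACING,
    DENSITY_LOBE_AREA,
    DENSITY_LOBE_COEF,
    DENSITY_MIN_DEGREE,
    DENSITY_SPACING,
    KERNEL_RATE_HIGH,
    SEED_CHAIN_GAP,
    SUPPORT_RADIUS,
    ModelParams,
)


class InitializationError(RuntimeError):
    """Raised when no valid cluster layout can be generated."""


@dataclass
class PatchGrid:
    """Per-patch resource and threat fields on a torus.

    ``threat`` is invariant over a run; ``resource`` degrades and diffuses.
    """

    resource: np.ndarray
    threat: np.ndarray
    toroidal: bool = True

    def __post_init__(self) -> None:
        if self.resource.shape != self.threat.shape:
            raise ValueError("resource and threat fields must share a shape")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.resource.shape

    @property
    def n_patches(self) -> int:
        return int(self.resource.size)

    def total_resource(self) -> float:
        return float(self.resource.sum())


@dataclass
class ClusterLayout:
    """Initial cell positions plus the generation metadata."""

    positions: np.ndarray          # (n, 2) continuous patch-unit coordinates
    density_class: str
    n_cells: int
    seed: Optional[int]
    radius: float = 0.0            # layout disc radius actually used
    attempts: int = 1              # whole-layout draws consumed
    centre: Tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)


def init_environment(params: ModelParams) -> PatchGrid:
    """Homogeneous resource/threat fields at the scenario's levels."""
    shape = (params.grid_width, params.grid_height)
    return PatchGrid(
        resource=np.full(shape, float(params.resource_level)),
        threat=np.full(shape, float(params.threat_level)),
    )


def toroidal_delta(p: np.ndarray, q: np.ndarray, dims: Sequence[float]) -> np.ndarray:
    """Component-wise shortest displacement from q to p on the torus."""
    delta = np.asarray(p, dtype=float) - np.asarray(q, dtype=float)
    dims = np.asarray(dims, dtype=float)
    return delta - dims * np.round(delta / dims)

def toroidal_distance(p, q, dims) -> float:
    """Shortest Euclidean distance between two points on the torus."""
    return float(np.linalg.norm(toroidal_delta(p, q, dims)))


def pairwise_adjacency(
    positions: np.ndarray, radius: float, dims: Sequence[float]
) -> np.ndarray:
    """Boolean adjacency matrix: toroidal distance <= radius (no self-loops)."""
    pos = np.mod(np.asarray(positions, dtype=float), np.asarray(dims, dtype=float))
    n = len(pos)
    adj = np.zeros((n, n), dtype=bool)
    if n > 1:
        tree = cKDTree(pos, boxsize=dims)
        for i, j in tree.query_pairs(radius):
            adj[i, j] = adj[j, i] = True
    return adj


def build_contact_network(
    positions: np.ndarray, link_radius: float, torus_dims: Sequence[float]
) -> nx.Graph:
    """Radius-based contact graph over cell positions on the torus.

    Nodes are cell indices carrying ``x``/``y`` attributes; an undirected
    edge joins every pair of cells whose toroidal centre-to-centre distance
    is at most ``link_radius``.  A cell's degree in this graph is its
    ``n_links`` property.
    """
    positions = np.asarray(positions, dtype=float)
    if len(positions) == 0:
        raise ValueError("positions must be non-empty")
    graph = nx.Graph()
    for i, (x, y) in enumerate(positions):
        graph.add_node(i, x=float(x), y=float(y))
    adj = pairwise_adjacency(positions, link_radius, torus_dims)
    graph.add_edges_from(zip(*np.nonzero(np.triu(adj))))
    return graph


def layout_radius(n_cells: int, area_per_cell: float) -> float:
    """Disc radius holding ``n_cells`` at the given area-per-cell."""
    return float(np.sqrt(n_cells * area_per_cell / np.pi))


def generate_cluster(
    params: ModelParams,
    rng: Optional[np.random.Generator] = None,
    max_layout_attempts: int = 1000,
    max_point_attempts: int = 2000,
) -> ClusterLayout:
    """Draw a random, connected, non-overlapping cluster layout.

    High-density clusters are grown as a single compact blob: cell centres
    are drawn uniformly in a disc of radius
    ``sqrt(n_cells * area(density) / pi)`` centred on the grid, accepted
    only when they keep the class spacing to every placed cell and land
    within ``link_radius`` of one, so the contact graph grows connected.
    Medium- and low-density clusters are grown as several dense lobes
    joined by single-cell-wide bridge chains — the loosely connected /
    branched morphologies of real clusters.  Layouts failing the class's
    minimum initial contact degree are redrawn.  Deterministic given the
    RNG state (or ``params.seed`` when no RNG is passed).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    dims = (float(params.grid_width), float(params.grid_height))
    centre = np.array([dims[0] / 2.0, dims[1] / 2.0])
    radius = layout_radius(params.n_cells, params.density_area)
    spacing = max(params.cell_extent,
                  DENSITY_SPACING.get(params.density_class, params.cell_extent))
    # tiny clusters cannot honour the full minimum-degree contract
    min_degree = min(DENSITY_MIN_DEGREE.get(params.density_class, 1),
                     max(1, params.n_cells // 3))
    lobe_coef = DENSITY_LOBE_COEF.get(params.density_class, 0.0)
    n_lobes = (max(2, round(lobe_coef * np.sqrt(params.n_cells)))
               if lobe_coef > 0 else 1)

    for attempt in range(1, max_layout_attempts + 1):
        if n_lobes <= 1:
            # cluster morphologies range from spherical to elongated
            lo = BLOB_ASPECT["base"] + BLOB_ASPECT["lo_slope"] * params.n_cells
            hi = min(BLOB_ASPECT["max"],
                     BLOB_ASPECT["base"] + BLOB_ASPECT["hi_slope"] * params.n_cells)
            aspect = rng.uniform(max(lo, 1.0), max(hi, lo, 1.0))
            angle = rng.uniform(0.0, np.pi)
            shape = (aspect, angle)
            kernel_cells = []
            if params.density_class == "high":
                kernel_cells = _pentagon_kernels(
                    rng, params.n_cells, centre, radius, dims, shape)
            positions = _sample_blob_layout(
                rng, params.n_cells - len(kernel_cells), centre, radius,
                spacing, params.link_radius, dims, max_point_attempts,
                shape=shape, seeded_with=kernel_cells,
            )
            if positions is not None:
                if kernel_cells:
                    positions = np.vstack([kernel_cells, positions])
                if min_degree > 1:
                    positions = _repair_min_degree(
                        rng, positions, min_degree, centre, radius, spacing,
                        params.link_radius, dims, max_point_attempts, shape,
                    )
        else:
            positions = _sample_lobed_layout(
                rng, params, n_lobes, centre, radius, spacing,
                dims, max_point_attempts,
            )
        if positions is None:
            continue  # packing failed; redraw the whole layout
        adj = pairwise_adjacency(positions, params.link_radius, dims)
        if _is_connected(adj) and adj.sum(axis=1).min() >= min_degree:
            return ClusterLayout(
                positions=positions,
                density_class=params.density_class,
                n_cells=params.n_cells,
                seed=params.seed,
                radius=radius,
                attempts=attempt,
                centre=(float(centre[0]), float(centre[1])),
                meta={"n_lobes": n_lobes},
            )
    raise InitializationError(
        f"no valid layout for n={params.n_cells}, "
        f"density={params.density_class!r} within {max_layout_attempts} attempts "
        "(violated constraint: connectivity / minimum initial degree "
        f">= {min_degree})"
    )


def _draw_in_disc(rng: np.random.Generator, centre: np.ndarray,
                  radius: float, dims: Sequence[float],
                  shape: Optional[tuple] = None) -> np.ndarray:
    """Uniform draw in a disc (sqrt-radius transform), wrapped on the torus.

    ``shape = (aspect, angle)`` stretches the disc into an equal-area
    ellipse with the given axis ratio and orientation.
    """
    r = radius * np.sqrt(rng.random())
    theta = 2.0 * np.pi * rng.random()
    p = r * np.array([np.cos(theta), np.sin(theta)])
    if shape is not None:
        aspect, angle = shape
        p = np.array([p[0] * np.sqrt(aspect), p[1] / np.sqrt(aspect)])
        c, s = np.cos(angle), np.sin(angle)
        p = np.array([c * p[0] - s * p[1], s * p[0] + c * p[1]])
    return np.mod(centre + p, dims)


def _sample_blob_layout(
    rng: np.random.Generator,
    n: int,
    centre: np.ndarray,
    radius: float,
    spacing: float,
    link_radius: float,
    dims: Sequence[float],
    max_point_attempts: int,
    existing: Optional[list] = None,
    hard_min_sep: float = 0.0,
    shape: Optional[tuple] = None,
    seeded_with: Optional[list] = None,
) -> Optional[np.ndarray]:
    """Sequential adjacency-constrained dart-throwing in a disc.

    New cells must keep ``spacing`` to cells of this blob and land within
    ``link_radius`` of one; cells listed in ``existing`` (other lobes,
    bridge chains) only impose the physical ``hard_min_sep``.  Cells in
    ``seeded_with`` count as part of this blob but are not returned.
    """
    n_seeded = len(seeded_with) if seeded_with else 0
    placed: list[np.ndarray] = list(seeded_with) if seeded_with else []
    others = np.array(existing) if existing else None
    for _ in range(n):
        for _ in range(max_point_attempts):
            p = _draw_in_disc(rng, centre, radius, dims, shape)
            if others is not None:
                d_other = np.linalg.norm(
                    toroidal_delta(p, others, dims), axis=1)
                if d_other.min() < hard_min_sep:
                    continue
            if not placed:
                placed.append(p)
                break
            dists = np.linalg.norm(
                toroidal_delta(p, np.array(placed), dims), axis=1)
            if dists.min() >= spacing and dists.min() <= min(
                    link_radius, SUPPORT_RADIUS):
                placed.append(p)
                break
        else:
            return None  # could not place this cell; caller redraws layout
    return np.array(placed[n_seeded:])


def _pentagon_kernels(
    rng: np.random.Generator,
    n: int,
    centre: np.ndarray,
    radius: float,
    dims: Sequence[float],
    shape: Optional[tuple],
) -> list:
    """Cohesive 6-cell kernels spread through a dense blob.

    A regular pentagon of circumradius 0.505 plus its centre has every
    cell pair between 0.505 and 0.96 apart: all six cells are mutually
    linked (degree >= 5 for life) while respecting both the physical
    non-overlap separation and the anoikis support radius.
    """
    k = max(2, round(KERNEL_RATE_HIGH * n))
    while k > 1 and 6 * k > n - 2:
        k -= 1  # kernels cannot outgrow the cluster
    if 6 * k > n - 2:
        return []
    while k >= 1:
        sep = 2.1
        while sep >= 1.7:
            centers: list = []
            for _ in range(k):
                for _ in range(120):
                    c = _draw_in_disc(rng, centre, 0.75 * radius, dims, shape)
                    if not centers or np.linalg.norm(
                            toroidal_delta(c, np.array(centers), dims),
                            axis=1).min() >= sep:
                        centers.append(c)
                        break
                else:
                    break
            if len(centers) == k:
                cells = []
                for c in centers:
                    cells.append(np.mod(c, dims))
                    theta = rng.uniform(0.0, 2.0 * np.pi)
                    for j in range(5):
                        ang = theta + j * 2.0 * np.pi / 5.0
                        cells.append(np.mod(
                            c + 0.505 * np.array([np.cos(ang), np.sin(ang)]),
                            dims))
                return cells
            sep *= 0.95
        k -= 1
    return []


def _repair_min_degree(
    rng: np.random.Generator,
    positions: np.ndarray,
    min_degree: int,
    centre: np.ndarray,
    radius: float,
    spacing: float,
    link_radius: float,
    dims: Sequence[float],
    max_point_attempts: int,
    shape: Optional[tuple],
    max_rounds: int = 30,
) -> Optional[np.ndarray]:
    """Replace under-connected cells instead of redrawing whole layouts."""
    n = len(positions)
    for _ in range(max_rounds):
        adj = pairwise_adjacency(positions, link_radius, dims)
        degrees = adj.sum(axis=1)
        bad = degrees < min_degree
        if not bad.any():
            return positions
        keep = positions[~bad]
        if len(keep) < max(min_degree + 1, n // 2):
            return None  # too mangled; caller redraws from scratch
        regrown = _sample_blob_layout(
            rng, int(bad.sum()), centre, radius, spacing, link_radius,
            dims, max_point_attempts, shape=shape,
            existing=None, seeded_with=list(keep),
        )
        if regrown is None:
            return None
        positions = np.vstack([keep, regrown])
    return None


def _sample_lobed_layout(
    rng: np.random.Generator,
    params: ModelParams,
    n_lobes: int,
    centre: np.ndarray,
    radius: float,
    spacing: float,
    dims: Sequence[float],
    max_point_attempts: int,
) -> Optional[np.ndarray]:
    """Multi-lobe layout: dense lobes joined by degree-2 bridge chains."""
    n = params.n_cells
    lobe_area = DENSITY_LOBE_AREA.get(params.density_class, 1.0)
    chain_gap = SEED_CHAIN_GAP.get(params.density_class, 2.2)
    for m in range(n_lobes, 0, -1):
        if m == 1:
            return _sample_blob_layout(
                rng, n, centre, radius, spacing,
                params.link_radius, dims, max_point_attempts,
            )
        r_lobe = float(np.sqrt((n / m) * lobe_area / np.pi))
        # seeds far enough apart that an open stretch of bridge remains
        # between the lobe rims (those cells are the breakable links);
        # the seed disc must hold m points at that separation comfortably
        separation = 2.0 * r_lobe + chain_gap
        enclosing = {2: 0.58, 3: 0.65, 4: 0.78, 5: 0.95}.get(min(m, 5), 1.15)
        seeds = _place_seeds(rng, m, centre,
                             max(radius - r_lobe, 1.2 * enclosing * separation),
                             separation, dims)
        if seeds is None:
            continue  # too many lobes for the disc; try fewer
        chain = _bridge_chains(rng, seeds, dims, params.cell_extent, r_lobe)
        # every lobe needs its 4-cell kernel plus room to grow a rim
        if 4 * m + len(chain) > n:
            continue
        budget = n - 4 * m - len(chain)
        shares = np.full(m, budget // m)
        shares[rng.permutation(m)[: budget % m]] += 1
        cells: list[np.ndarray] = list(chain)
        ok = True
        for seed, share in zip(seeds, shares):
            # cohesive nucleus: the seed plus a tight triangle, all four
            # pairwise linked, so every kernel cell keeps >= 3 links
            kernel = [seed]
            theta = rng.uniform(0, 2 * np.pi)
            for j in range(3):
                ang = theta + j * 2 * np.pi / 3 + rng.uniform(-0.2, 0.2)
                kernel.append(np.mod(
                    seed + 0.52 * np.array([np.cos(ang), np.sin(ang)]), dims))
            if cells and min(
                    np.linalg.norm(toroidal_delta(q, np.array(cells), dims),
                                   axis=1).min() for q in kernel[1:]
            ) < params.cell_extent:
                ok = False  # nucleus collides with a bridge; redraw layout
                break
            grown = _sample_blob_layout(
                rng, int(share), seed,
                float(np.sqrt(((share + 4) * lobe_area) / np.pi)) + 0.3,
                spacing, params.link_radius, dims, max_point_attempts,
                existing=cells, hard_min_sep=params.cell_extent,
                seeded_with=kernel,
            )
            if grown is None:
                ok = False
                break
            cells.extend(kernel)
            cells.extend(grown)
        if ok:
            return np.array(cells)
    return None


def _place_seeds(
    rng: np.random.Generator,
    m: int,
    centre: np.ndarray,
    radius: float,
    separation: float,
    dims: Sequence[float],
    max_rounds: int = 25,
    tries_per_round: int = 200,
) -> Optional[list]:
    """Spread m lobe seeds in the disc; separation shrinks a little if it
    can't fit, but never below ~85% of the requested value (the bridge gap
    between lobes must survive)."""
    sep = separation
    floor = 0.85 * separation
    for _ in range(max_rounds):
        if sep < floor:
            return None
        for _ in range(tries_per_round):
            seeds = [_draw_in_disc(rng, centre, radius, dims)]
            for _ in range(m - 1):
                for _ in range(50):
                    p = _draw_in_disc(rng, centre, radius, dims)
                    d = np.linalg.norm(
                        toroidal_delta(p, np.array(seeds), dims), axis=1)
                    if d.min() >= sep:
                        seeds.append(p)
                        break
                else:
                    break
            if len(seeds) == m:
                return seeds
        sep *= 0.92
    return None


def _bridge_chains(
    rng: np.random.Generator,
    seeds: list,
    dims: Sequence[float],
    hard_min_sep: float,
    r_lobe: float = 0.0,
) -> list:
    """Chains of cells along the seed minimum spanning tree edges.

    Cells falling inside a lobe's footprint (closer than ``r_lobe`` to an
    endpoint seed) are dropped: the lobe itself provides connectivity
    there, and only the open stretch between rims forms the breakable,
    degree-2 part of the bridge.
    """
    m = len(seeds)
    pts = np.array(seeds)
    dist = np.array([[toroidal_distance(pts[i], pts[j], dims)
                      for j in range(m)] for i in range(m)])
    chain: list = []
    # Prim's MST over the seeds
    in_tree = {0}
    while len(in_tree) < m:
        best = None
        for i in in_tree:
            for j in range(m):
                if j in in_tree:
                    continue
                if best is None or dist[i, j] < dist[best[0], best[1]]:
                    best = (i, j)
        i, j = best
        in_tree.add(j)
        d = dist[i, j]
        n_steps = max(int(np.ceil(d / CHAIN_SPACING)), 1)
        step_vec = toroidal_delta(pts[j], pts[i], dims) / n_steps
        normal = np.array([-step_vec[1], step_vec[0]])
        normal /= max(np.linalg.norm(normal), 1e-12)
        cut = max(r_lobe - 0.25, 0.0)
        for s in range(1, n_steps):
            jitter = rng.uniform(-0.12, 0.12)
            p = np.mod(pts[i] + s * step_vec + jitter * normal, dims)
            if min(toroidal_distance(p, pts[i], dims),
                   toroidal_distance(p, pts[j], dims)) < cut:
                continue  # inside a lobe footprint; the lobe links there
            if chain:
                d_prev = np.linalg.norm(
                    toroidal_delta(p, np.array(chain), dims), axis=1)
                if d_prev.min() < hard_min_sep:
                    continue
            chain.append(p)
    return chain


def _is_connected(adj: np.ndarray) -> bool:
    """Connectivity of the graph given by a boolean adjacency matrix (BFS)."""
    n = len(adj)
    if n == 0:
        return False
    seen = np.zeros(n, dtype=bool)
    frontier = np.zeros(n, dtype=bool)
    frontier[0] = seen[0] = True
    while frontier.any():
        frontier = (adj[frontier].any(axis=0)) & ~seen
        seen |= frontier
    return bool(seen.all())
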