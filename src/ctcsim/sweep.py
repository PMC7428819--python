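"""Factorial sweep engine and quartile summaries.

A :class:`SweepDesign` spans the factorial grid density x size x threat x
resource; every design cell is run for ``n_replicates`` independent
replicates.  Each replicate's seed is derived from ``(base_seed,
cell_index, replicate)`` through ``numpy.random.SeedSequence``, so results
are reproducible and independent of execution order — running the design
cells in any order, or any subset, yields identical rows.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .metrics import outcome_from_run
from .params import RESOURCE_LEVELS, THREAT_LEVELS, ModelParams
from .simulate import RunResult, run

#: Columns of the long-format sweep table, one row per run.
SWEEP_COLUMNS = [
    "density", "n_cells", "threat", "resource", "replicate", "seed",
    "n_final", "components", "SR", "SI", "end_tick", "end_reason",
    "median_energy", "median_resource",
]


@dataclass
class SweepDesign:
    """Factorial design over the four swept parameters."""

    density_classes: Sequence[str] = ("high", "medium", "low")
    sizes: Sequence[int] = (20, 40, 80, 100)
    threat_levels: Sequence[float] = (THREAT_LEVELS["very_low"],)
    resource_levels: Sequence[float] = (RESOURCE_LEVELS["very_high"],)
    n_replicates: int = 200
    base_seed: int = 0

    def cells(self) -> List[Tuple[str, int, float, float]]:
        """Design cells in their canonical (seeding) order."""
        return list(itertools.product(
            self.density_classes, self.sizes,
            self.threat_levels, self.resource_levels,
        ))

    @property
    def n_runs(self) -> int:
        return len(self.cells()) * self.n_replicates


def derive_seed(base_seed: int, cell_index: int, replicate: int) -> int:
    """Collision-free per-run seed, independent of execution order."""
    ss = np.random.SeedSequence([int(base_seed), int(cell_index), int(replicate)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_cell(
    params_base: ModelParams,
    density: str,
    n_cells: int,
    threat: float,
    resource: float,
    n_replicates: int,
    base_seed: int,
    cell_index: int,
) -> List[dict]:
    """All replicates of one design cell, as sweep-table rows."""
    rows = []
    for rep in range(n_replicates):
        seed = derive_seed(base_seed, cell_index, rep)
        params = params_base.replace(
            density_class=density, n_cells=n_cells,
            threat_level=threat, resource_level=resource, seed=seed,
        )
        row = {
            "density": density, "n_cells": n_cells,
            "threat": threat, "resource": resource,
            "replicate": rep, "seed": seed,
        }
        try:
            result = run(params)
            outcome = outcome_from_run(result)
            row.update(
                n_final=result.n_final,
                components=outcome.components,
                SR=outcome.SR,
                SI=outcome.SI,
                end_tick=result.end_tick,
                end_reason=result.end_reason,
                median_energy=result.median_energy,
                median_resource=result.median_resource,
            )
        except Exception as exc:  # a failed run is recorded, not fatal
            row.update(
                n_final=np.nan, components=np.nan, SR=np.nan, SI=np.nan,
                end_tick=np.nan, end_reason=f"error: {exc}",
                median_energy=np.nan, median_resource=np.nan,
            )
        rows.append(row)
    return rows


def run_sweep(
    design: SweepDesign,
    params_base: Optional[ModelParams] = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Execute the full design; returns the long-format sweep table."""
    if params_base is None:
        params_base = ModelParams()
    cells = design.cells()
    if not cells or design.n_replicates < 1:
        raise ValueError("sweep design must be non-empty")
    rows: List[dict] = []
    for ci, (density, n_cells, threat, resource) in enumerate(cells):
        if progress:
            print(f"[sweep] cell {ci + 1}/{len(cells)}: density={density} "
                  f"n={n_cells} threat={threat} resource={resource}")
        rows.extend(run_cell(
            params_base, density, n_cells, threat, resource,
            design.n_replicates, design.base_seed, ci,
        ))
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def summarize(
    table: pd.DataFrame,
    group_keys: Iterable[str] = ("density", "n_cells"),
    value_cols: Sequence[str] = ("SR", "SI"),
) -> pd.DataFrame:
    """Boxplot-style quartile summaries per group.

    For every group and value column: median, first/third quartile
    (linear-interpolation quantiles), min, max and the 1.5*IQR outlier
    fences.  Empty groups are dropped.
    """
    if table.empty:
        raise ValueError("cannot summarise an empty sweep table")
    group_keys = list(group_keys)
    records = []
    for keys, grp in table.groupby(group_keys, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        rec = dict(zip(group_keys, keys))
        rec["n_runs"] = len(grp)
        for col in value_cols:
            vals = grp[col].dropna().to_numpy()
            if vals.size == 0:
                continue
            q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
            iqr = q3 - q1
            rec[f"{col}_median"] = med
            rec[f"{col}_q1"] = q1
            rec[f"{col}_q3"] = q3
            rec[f"{col}_min"] = vals.min()
            rec[f"{col}_max"] = vals.max()
            rec[f"{col}_fence_low"] = q1 - 1.5 * iqr
            rec[f"{col}_fence_high"] = q3 + 1.5 * iqr
        records.append(rec)
    return pd.DataFrame(records)


def median_sr(table: pd.DataFrame, **filters) -> float:
    """Median per-run survival ratio of the rows matching ``filters``."""
    return _median_of(table, "SR", filters)


def median_si(table: pd.DataFrame, **filters) -> float:
    """Median per-run stability index of the rows matching ``filters``."""
    return _median_of(table, "SI", filters)


def _median_of(table: pd.DataFrame, col: str, filters: dict) -> float:
    mask = pd.Series(True, index=table.index)
    for key, val in filters.items():
        if isinstance(val, float):
            mask &= np.isclose(table[key], val)
        else:
            mask &= table[key] == val
    vals = table.loc[mask, col].dropna()
    if vals.empty:
        raise ValueError(f"no rows match {filters}")
    return float(vals.median())
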