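"""Outcome statistics: survival ratio, stability index, fragmentation.

The survival ratio ``SR = N_final / N_initial`` measures the resilience of
a cluster — what fraction of its cells outlived the run.  The stability
index ``SI = SR / components`` normalises that by the number of connected
components the survivors are scattered across, so it measures resistance
to dissociation: an intact cluster has ``SI = SR``, and the wider the gap
``SR - SI``, the more the cluster fragmented.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .simulate import RunResult


def survival_ratio(n_final: int, n_initial: int) -> float:
    """Fraction of the initial cells alive at the end of a run."""
    if n_initial < 1:
        raise ValueError("n_initial must be >= 1")
    if not (0 <= n_final <= n_initial):
        raise ValueError("n_final must lie in [0, n_initial]")
    return n_final / n_initial


def count_components(network: nx.Graph) -> int:
    """Connected components of the living-cell contact graph.

    A single isolated node is itself a component; the empty graph has 0.
    """
    return nx.number_connected_components(network)


def stability_index(sr: float, components: int) -> float:
    """Survival ratio normalised by the number of surviving components.

    Defined as 0 when there are no components (total extinction): the
    least-stable outcome, keeping ``SI <= SR`` everywhere.
    """
    if not (0.0 <= sr <= 1.0):
        raise ValueError("SR must lie in [0, 1]")
    if components < 0:
        raise ValueError("components must be >= 0")
    if components == 0:
        if sr > 0:
            raise ValueError("components can be 0 only when SR is 0")
        return 0.0
    return sr / components


@dataclass(frozen=True)
class OutcomeRecord:
    """Per-run outcome bundle derived from a run's end state."""

    SR: float
    SI: float
    components: int
    n_initial: int
    n_final: int

    @property
    def fragmentation_gap(self) -> float:
        """``SR - SI``; 0 for an intact (or extinct) cluster, > 0 otherwise."""
        return self.SR - self.SI


def outcome_from_run(result: RunResult) -> OutcomeRecord:
    """Compute SR/SI/fragmentation from a finished run."""
    sr = survival_ratio(result.n_final, result.n_initial)
    si = stability_index(sr, result.components_final)
    return OutcomeRecord(
        SR=sr,
        SI=si,
        components=result.components_final,
        n_initial=result.n_initial,
        n_final=result.n_final,
    )
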