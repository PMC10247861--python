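"""Remeeting-time histories and the perturbation-guided vertex selection rule.

Along a lineage of edge removals the remeeting-time vector is recorded after
every removal: tau(0) on the regular input graph, tau(1) after the first
removal, and so on. The j-th edge is removed from the vertex

    n_j = argmax_i  Delta^j tau_i,

where Delta^j tau_i is, by default, the moving difference
tau_i(j) - tau_i(j-1) (and tau_i(0) itself for j = 0). The full forward
difference sum_p (-1)^(j-p) C(j,p) tau_i(p) is available as an alternative
rule. Ties are broken by lowest vertex index (within a small tolerance, so
vertex-transitive inputs deterministically select vertex 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

__all__ = ["TauHistory", "moving_difference", "forward_difference", "select_vertex"]

#: values within this tolerance of the maximum count as tied
TIE_TOL = 1e-9


@dataclass
class TauHistory:
    """Per-vertex remeeting-time sequences along one removal lineage.

    ``taus[j]`` is the remeeting-time vector after j removals; ``removed_from``
    lists the vertex each edge was removed from. Vertex labels are stable
    across the lineage (no relabeling).
    """

    taus: list = field(default_factory=list)
    removed_from: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.taus) != len(self.removed_from) + 1:
            raise ValueError("history length must equal removals performed + 1")

    @property
    def n_removals(self) -> int:
        return len(self.removed_from)

    def extended(self, tau: np.ndarray, vertex: int) -> "TauHistory":
        return TauHistory(self.taus + [tau], self.removed_from + [vertex])


def moving_difference(history: TauHistory, j: int) -> np.ndarray:
    """Delta^j tau_i = tau_i(j) - tau_i(j-1); tau_i(0) itself for j = 0."""
    if j == 0:
        return np.asarray(history.taus[0])
    if j < 0 or j >= len(history.taus):
        raise ValueError(f"history has no entry {j}")
    return np.asarray(history.taus[j]) - np.asarray(history.taus[j - 1])


def forward_difference(history: TauHistory, j: int) -> np.ndarray:
    """Full forward difference sum_p (-1)^(j-p) C(j,p) tau_i(p)."""
    if j < 0 or j >= len(history.taus):
        raise ValueError(f"history has no entry {j}")
    out = np.zeros_like(np.asarray(history.taus[0], dtype=float))
    for p in range(j + 1):
        out += (-1) ** (j - p) * comb(j, p) * np.asarray(history.taus[p])
    return out


def select_vertex(history: TauHistory, j: int | None = None, rule: str = "moving") -> int:
    """Vertex from which the next edge is removed.

    A pure function of the history: the argmax of Delta^j tau (with
    j = removals performed so far unless given), lowest index on ties. A
    previously used vertex is selected again exactly when it is the argmax.
    """
    if j is None:
        j = history.n_removals
    if rule == "moving":
        d = moving_difference(history, j)
    elif rule == "forward":
        d = forward_difference(history, j)
    else:
        raise ValueError("rule must be 'moving' or 'forward'")
    return int(np.flatnonzero(d >= d.max() - TIE_TOL)[0])
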