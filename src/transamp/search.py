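"""Iterative guided edge-removal search for transient amplifiers.

Starting from a connected k-regular input graph, the search repeatedly removes
single edges. At each repetition l = 1..l_max every pool member selects the
vertex with the largest remeeting-time difference (see :mod:`.guidance`) and
spawns one child per edge incident to that vertex. Children that become
disconnected are discarded; the pooled children of one step are deduplicated
by their rounded normalized-Laplacian spectrum (cospectral proxy for
isomorphism). In greedy mode only the ``filter_size`` children with the
smallest algebraic connectivity lambda_2 survive to the next repetition (the
enumerative mode keeps all). Every retained child is then tested with the
weak-selection criterion N_eff > N; hits are recorded as transient-amplifier
candidates and continue to be expanded (consecutive amplifiers occur).

The removal budget defaults to 1 + (k-2)N/2: a k-regular graph has kN/2 edges
and a connected graph needs at least N-1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from ._core import (
    adjacency,
    coalescence_from_adj,
    graph_from_adjacency,
    is_connected_adj,
    normalized_spectrum_adj,
    standard_spectrum_adj,
)
from .coalescence import DEFAULT_AMPLIFIER_TOL
from .guidance import TauHistory, select_vertex
from .graphs import canonical_key
from .spectral import SpectralDensity, density_distance, ensemble_density, interlacing_holds

logger = logging.getLogger(__name__)

__all__ = [
    "SearchConfig",
    "AmplifierRecord",
    "DynamicsTrace",
    "SearchResult",
    "CampaignStats",
    "CampaignResult",
    "run_search",
    "run_campaign",
    "count_nonisomorphic",
    "spectral_dynamics",
    "auto_max_removals",
]


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the guided search (defaults follow the study conditions)."""

    mode: str = "greedy"                 # 'greedy' or 'enumerative'
    filter_size: int | None = 500        # pool cap #_G; None = unbounded
    filter_measure: str = "lambda2"      # 'lambda2' or 'mu2'
    max_removals: int | None = None      # None = auto bound 1 + (k-2)N/2
    amplifier_tol: float = DEFAULT_AMPLIFIER_TOL
    cospectral_decimals: int = 9
    record_dynamics: bool = False
    guidance_rule: str = "moving"        # 'moving' or 'forward'
    expand_amplifiers: bool = True
    check_interlacing: bool = False

    def __post_init__(self):
        if self.mode not in ("greedy", "enumerative"):
            raise ValueError("mode must be 'greedy' or 'enumerative'")
        if self.filter_measure not in ("lambda2", "mu2"):
            raise ValueError("filter_measure must be 'lambda2' or 'mu2'")
        if self.filter_size is not None and self.filter_size < 1:
            raise ValueError("filter_size must be >= 1")
        if self.max_removals is not None and self.max_removals < 1:
            raise ValueError("max_removals must be >= 1")


@dataclass(frozen=True)
class AmplifierRecord:
    graph: nx.Graph
    n_eff: float
    removals: int
    lineage: tuple[tuple[int, int], ...]
    input_id: object = None


@dataclass
class _TraceRow:
    step: int
    member_id: int
    parent_id: int | None
    lam2: float
    n_eff: float
    is_amplifier: bool
    spectrum: np.ndarray | None


@dataclass
class DynamicsTrace:
    rows: list = field(default_factory=list)
    pool_sizes: dict = field(default_factory=dict)
    lam2_stats: dict = field(default_factory=dict)   # step -> (min, mean, max)
    record_dynamics: bool = False


@dataclass
class SearchResult:
    amplifiers: list
    trace: DynamicsTrace
    input_id: object = None


def auto_max_removals(n: int, k: int) -> int:
    """Upper bound on useful edge removals: 1 + (k-2)N/2."""
    return 1 + ((k - 2) * n) // 2


class _Member:
    __slots__ = ("mid", "parent_id", "adj", "history", "lineage", "lam", "mu")

    def __init__(self, mid, parent_id, adj, history, lineage, lam, mu=None):
        self.mid = mid
        self.parent_id = parent_id
        self.adj = adj
        self.history = history
        self.lineage = lineage
        self.lam = lam
        self.mu = mu


def _spectrum_key(lam: np.ndarray, decimals: int) -> bytes:
    return (np.round(lam, decimals) + 0.0).tobytes()


def run_search(g_in: nx.Graph, config: SearchConfig | None = None, input_id=None) -> SearchResult:
    """Run the guided edge-removal search from one regular input graph."""
    cfg = config or SearchConfig()
    adj0 = adjacency(g_in)
    n = adj0.shape[0]
    deg = adj0.sum(axis=1)
    if not is_connected_adj(adj0):
        raise ValueError("input graph must be connected")
    k = int(deg[0])
    if not np.all(deg == k) or k < 3:
        raise ValueError("input graph must be k-regular with k >= 3")

    max_rem = cfg.max_removals if cfg.max_removals is not None else auto_max_removals(n, k)
    dec = cfg.cospectral_decimals
    need_mu = cfg.filter_measure == "mu2" or cfg.check_interlacing

    _, tau0, _, neff0 = coalescence_from_adj(adj0)
    lam0 = normalized_spectrum_adj(adj0)
    mu0 = standard_spectrum_adj(adj0) if need_mu else None
    root = _Member(0, None, adj0, TauHistory([tau0], []), (), lam0, mu0)

    trace = DynamicsTrace(record_dynamics=cfg.record_dynamics)
    trace.pool_sizes[0] = 1
    trace.lam2_stats[0] = (float(lam0[1]),) * 3
    trace.rows.append(
        _TraceRow(0, 0, None, float(lam0[1]), neff0, False,
                  lam0.copy() if cfg.record_dynamics else None)
    )

    amplifiers: dict[bytes, AmplifierRecord] = {}
    pool = [root]
    next_id = 1

    for step in range(1, max_rem + 1):
        seen: set[bytes] = set()
        candidates = []  # (lam2, key, lam, adj, parent, edge, mu)
        for member in pool:
            v = select_vertex(member.history, rule=cfg.guidance_rule)
            for u in np.flatnonzero(member.adj[v]):
                u = int(u)
                child = member.adj.copy()
                child[v, u] = child[u, v] = 0.0
                if child[v].sum() == 0 or child[u].sum() == 0 or not is_connected_adj(child):
                    continue
                lam = normalized_spectrum_adj(child)
                mu = standard_spectrum_adj(child) if need_mu else None
                if cfg.check_interlacing:
                    parent_mu = member.mu if member.mu is not None else standard_spectrum_adj(member.adj)
                    std_ok, norm_ok = interlacing_holds(parent_mu, member.lam, mu, lam)
                    if not (std_ok and norm_ok):
                        raise RuntimeError(
                            f"interlacing violated removing edge ({v},{u}) at step {step}"
                        )
                key = _spectrum_key(lam, dec)
                if key in seen:
                    continue
                seen.add(key)
                candidates.append((float(lam[1]), key, lam, child, member, (v, u), mu))

        if not candidates:
            logger.info("pool empty at step %d", step)
            break

        if cfg.mode == "greedy" and cfg.filter_size is not None and len(candidates) > cfg.filter_size:
            # ties in the measure are broken by the (unique, post-dedup) rounded spectrum
            if cfg.filter_measure == "lambda2":
                candidates.sort(key=lambda c: (c[0], tuple(np.frombuffer(c[1]))))
            else:
                candidates.sort(key=lambda c: (float(c[6][1]), tuple(np.frombuffer(c[1]))))
            candidates = candidates[: cfg.filter_size]

        new_pool = []
        lam2s = []
        for lam2, key, lam, child, parent, edge, mu in candidates:
            _, tau, pi, n_eff = coalescence_from_adj(child)
            hist = parent.history.extended(tau, edge[0])
            lineage = parent.lineage + (edge,)
            m = _Member(next_id, parent.mid, child, hist, lineage, lam, mu)
            next_id += 1
            is_amp = n_eff - n > cfg.amplifier_tol
            if is_amp:
                rec = AmplifierRecord(
                    graph_from_adjacency(child), n_eff, step, lineage, input_id
                )
                amplifiers.setdefault(key, rec)
            trace.rows.append(
                _TraceRow(step, m.mid, parent.mid, lam2, n_eff, is_amp,
                          lam.copy() if cfg.record_dynamics else None)
            )
            lam2s.append(lam2)
            if is_amp and not cfg.expand_amplifiers:
                continue
            new_pool.append(m)

        trace.pool_sizes[step] = len(new_pool)
        trace.lam2_stats[step] = (min(lam2s), float(np.mean(lam2s)), max(lam2s))
        logger.debug("step %d: %d candidates retained, %d amplifiers so far",
                     step, len(new_pool), len(amplifiers))
        pool = new_pool

    return SearchResult(list(amplifiers.values()), trace, input_id)


@dataclass(frozen=True)
class CampaignStats:
    n_inputs: int
    n_amplifying_inputs: int
    total_amplifiers: int
    nonisomorphic_amplifiers: int
    mean_degree_of_amplifiers: float


@dataclass
class CampaignResult:
    stats: CampaignStats
    records: list
    results: list  # per-input SearchResult


def run_campaign(inputs: Sequence[nx.Graph], config: SearchConfig | None = None) -> CampaignResult:
    """Run the guided search over a set of same-order regular input graphs."""
    inputs = list(inputs)
    if not inputs:
        raise ValueError("empty input set")
    orders = {g.number_of_nodes() for g in inputs}
    if len(orders) != 1:
        raise ValueError(f"inputs must share one order, got {sorted(orders)}")

    results = []
    records: list[AmplifierRecord] = []
    amplifying = 0
    for i, g in enumerate(inputs):
        input_id = g.graph.get("label", i)
        res = run_search(g, config, input_id=input_id)
        results.append(res)
        records.extend(res.amplifiers)
        if res.amplifiers:
            amplifying += 1
        logger.info("input %s: %d amplifier records", input_id, len(res.amplifiers))

    noniso, reps = count_nonisomorphic(records)
    mean_deg = (
        float(np.mean([2 * g.number_of_edges() / g.number_of_nodes() for g in reps]))
        if reps
        else math.nan
    )
    stats = CampaignStats(len(inputs), amplifying, len(records), noniso, mean_deg)
    return CampaignResult(stats, records, results)


def count_nonisomorphic(records: Iterable[AmplifierRecord]) -> tuple[int, list[nx.Graph]]:
    """Number of canonical-key-distinct amplifier graphs and one representative each."""
    reps: dict[str, nx.Graph] = {}
    for rec in records:
        reps.setdefault(canonical_key(rec.graph), rec.graph)
    return len(reps), list(reps.values())


def _amplifier_bound_ids(trace: DynamicsTrace) -> set[int]:
    """Members whose subtree (including themselves) contains an amplifier."""
    children: dict[int, list[int]] = {}
    by_id = {}
    for row in trace.rows:
        by_id[row.member_id] = row
        if row.parent_id is not None:
            children.setdefault(row.parent_id, []).append(row.member_id)
    bound: set[int] = set()
    # rows are created in id order, so reverse order visits children first
    for row in reversed(trace.rows):
        if row.is_amplifier or any(c in bound for c in children.get(row.member_id, ())):
            bound.add(row.member_id)
    return bound


def spectral_dynamics(
    traces: Iterable[DynamicsTrace],
    sigma: float | None = None,
    grid: np.ndarray | None = None,
) -> tuple[list[dict], list[int]]:
    """Per-step ensemble densities of amplifier-bound vs other candidate graphs.

    A pool member at step l belongs to the amplifier-bound set iff itself or
    some descendant is an amplifier (for l = 0 this splits the input graphs
    into those that yield amplifiers and the rest). Returns per-step dicts with
    the two densities, their pointwise absolute difference and the spectral
    distance, plus the list of steps omitted because one set was empty.
    """
    per_step: dict[int, tuple[list, list]] = {}
    for trace in traces:
        if not trace.record_dynamics:
            raise ValueError("spectral_dynamics requires traces recorded with record_dynamics")
        bound = _amplifier_bound_ids(trace)
        for row in trace.rows:
            amp, non = per_step.setdefault(row.step, ([], []))
            (amp if row.member_id in bound else non).append(row.spectrum)

    out = []
    skipped = []
    for step in sorted(per_step):
        amp, non = per_step[step]
        if not amp or not non:
            skipped.append(step)
            logger.info("step %d omitted: amplifier-bound set %s, complement %s",
                        step, len(amp), len(non))
            continue
        phi_a = ensemble_density(amp, sigma=sigma, grid=grid)
        phi_n = ensemble_density(non, sigma=sigma, grid=grid)
        out.append(
            {
                "step": step,
                "n_amplifier_bound": len(amp),
                "n_other": len(non),
                "phi_amplifier": phi_a,
                "phi_other": phi_n,
                "abs_difference": np.abs(phi_a.values - phi_n.values),
                "distance": density_distance(phi_a, phi_n),
            }
        )
    return out, skipped
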