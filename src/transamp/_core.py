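"""Internal adjacency-matrix routines shared by the public modules.

Everything here operates on dense numpy adjacency matrices (float64, symmetric,
zero diagonal) so the search module can iterate over thousands of small
candidate graphs without paying networkx object-construction costs. Public
modules convert to/from :class:`networkx.Graph` at their boundaries.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

# above this many pair unknowns the coalescence system is solved sparsely
_DENSE_PAIR_LIMIT = 1600


def adjacency(g) -> np.ndarray:
    """Dense adjacency matrix of a networkx graph, rows ordered by sorted nodes."""
    import networkx as nx

    nodes = sorted(g.nodes())
    return nx.to_numpy_array(g, nodelist=nodes, dtype=np.float64)


def graph_from_adjacency(adj: np.ndarray):
    import networkx as nx

    return nx.from_numpy_array(adj, create_using=nx.Graph)


def is_connected_adj(adj: np.ndarray) -> bool:
    n = adj.shape[0]
    if n == 0:
        return False
    visited = np.zeros(n, dtype=bool)
    frontier = np.zeros(n, dtype=bool)
    visited[0] = frontier[0] = True
    while frontier.any():
        nxt = (adj[frontier] != 0).any(axis=0) & ~visited
        visited |= nxt
        frontier = nxt
    return bool(visited.all())


def normalized_laplacian_adj(adj: np.ndarray) -> np.ndarray:
    deg = adj.sum(axis=1)
    if (deg == 0).any():
        raise ValueError("normalized Laplacian undefined for isolated vertices")
    dinv = 1.0 / np.sqrt(deg)
    lap = -(adj * dinv[:, None]) * dinv[None, :]
    np.fill_diagonal(lap, 1.0)
    return lap


def standard_laplacian_adj(adj: np.ndarray) -> np.ndarray:
    lap = -adj.copy()
    np.fill_diagonal(lap, adj.sum(axis=1))
    return lap


def normalized_spectrum_adj(adj: np.ndarray, clip_tol: float = 1e-9) -> np.ndarray:
    """Sorted normalized-Laplacian eigenvalues, clipped to [0, 2] within tolerance."""
    lam = np.linalg.eigvalsh(normalized_laplacian_adj(adj))
    lam[np.abs(lam) <= clip_tol] = 0.0
    lam[np.abs(lam - 2.0) <= clip_tol] = 2.0
    return lam


def standard_spectrum_adj(adj: np.ndarray, clip_tol: float = 1e-9) -> np.ndarray:
    mu = np.linalg.eigvalsh(standard_laplacian_adj(adj))
    mu[np.abs(mu) <= clip_tol] = 0.0
    return mu


def pair_index(n: int) -> np.ndarray:
    """Map unordered vertex pairs (i<j) to linear indices 0..C(n,2)-1."""
    pidx = np.full((n, n), -1, dtype=np.int64)
    c = 0
    for i in range(n):
        for j in range(i + 1, n):
            pidx[i, j] = pidx[j, i] = c
            c += 1
    return pidx


def coalescence_from_adj(adj: np.ndarray):
    """Coalescing-random-walk quantities for one connected graph.

    Solves the C(N,2) linear system for pairwise coalescence times tau_ij
    (tau_ii = 0, and for i != j::

        tau_ij = 1 + 1/2 * sum_k (p_ik tau_jk + p_jk tau_ik),

    with step probabilities p_ij = 1/k_i on edges), then forms the remeeting
    times tau_i = 1 + sum_j p_ij tau_ij, the relative degrees
    pi_i = k_i / sum_j k_j and the effective population size
    N_eff = sum_i pi_i tau_i.

    Returns ``(tau_pair, tau_remeet, pi, n_eff)``.
    """
    n = adj.shape[0]
    if n < 2:
        raise ValueError("need at least 2 vertices")
    deg = adj.sum(axis=1)
    if (deg == 0).any() or not is_connected_adj(adj):
        raise ValueError("coalescence times require a connected graph")

    nbrs = [np.flatnonzero(adj[i]) for i in range(n)]
    pidx = pair_index(n)
    npairs = n * (n - 1) // 2

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        half_pi = 0.5 / deg[i]
        for j in range(i + 1, n):
            p = pidx[i, j]
            rows.append(p)
            cols.append(p)
            vals.append(1.0)
            for k in nbrs[i]:
                if k != j:  # tau_jj = 0 drops out
                    rows.append(p)
                    cols.append(pidx[j, k])
                    vals.append(-half_pi)
            half_pj = 0.5 / deg[j]
            for k in nbrs[j]:
                if k != i:
                    rows.append(p)
                    cols.append(pidx[i, k])
                    vals.append(-half_pj)

    b = np.ones(npairs)
    if npairs <= _DENSE_PAIR_LIMIT:
        mat = np.zeros((npairs, npairs))
        np.add.at(mat, (np.asarray(rows), np.asarray(cols)), np.asarray(vals))
        x = np.linalg.solve(mat, b)
    else:
        mat = sp.csc_matrix((vals, (rows, cols)), shape=(npairs, npairs))
        x = spla.spsolve(mat, b)

    tau_pair = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    tau_pair[iu] = x
    tau_pair += tau_pair.T

    tau_remeet = 1.0 + (adj * tau_pair).sum(axis=1) / deg
    pi = deg / deg.sum()
    n_eff = float(pi @ tau_remeet)
    return tau_pair, tau_remeet, pi, n_eff
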