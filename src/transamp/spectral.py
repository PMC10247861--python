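"""Laplacian spectra, interlacing checks, smoothed spectral density and the
spectral pseudometric.

For a graph with adjacency matrix A and degree matrix D, the standard
Laplacian is L = D - A and the normalized Laplacian is
Lambda = I - D^{-1/2} A D^{-1/2}. Their sorted spectra are written
mu_1 <= ... <= mu_N and 0 <= lambda_1 <= ... <= lambda_N <= 2; the second
smallest eigenvalues mu_2 and lambda_2 are the algebraic connectivities.

Removing an edge e interlaces the spectra:

* standard:    mu_{i-1}(G) <= mu_i(G-e) <= mu_i(G)           (i = 2..N)
* normalized:  lambda_{i-1}(G) <= lambda_i(G-e) <= lambda_{i+1}(G)  (i = 2..N-1)

so standard-Laplacian eigenvalues never increase under edge removal, whereas
normalized-Laplacian eigenvalues may (Braess's paradox for lambda_2).

The smoothed spectral density convolves a spectrum with a Gaussian kernel of
width sigma (default 1/(3N)); the L1 distance between two such densities on
[0, 2] is a pseudometric on graphs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from ._core import (
    adjacency,
    normalized_laplacian_adj,
    normalized_spectrum_adj,
    standard_laplacian_adj,
    standard_spectrum_adj,
)

__all__ = [
    "SpectralSummary",
    "SpectralDensity",
    "laplacians",
    "spectral_summary",
    "interlacing_check",
    "interlacing_holds",
    "default_sigma",
    "spectral_density",
    "density_distance",
    "spectral_distance",
    "ensemble_density",
]

DEFAULT_GRID = np.linspace(0.0, 2.0, 2001)


@dataclass(frozen=True)
class SpectralSummary:
    mu: np.ndarray
    lam: np.ndarray

    @property
    def mu2(self) -> float:
        return float(self.mu[1])

    @property
    def lam2(self) -> float:
        return float(self.lam[1])


@dataclass(frozen=True)
class SpectralDensity:
    grid: np.ndarray
    values: np.ndarray
    sigma: float


def laplacians(g: nx.Graph) -> tuple[np.ndarray, np.ndarray]:
    """(standard, normalized) Laplacian matrices; errors on isolated vertices."""
    adj = adjacency(g)
    return standard_laplacian_adj(adj), normalized_laplacian_adj(adj)


def spectral_summary(g: nx.Graph) -> SpectralSummary:
    adj = adjacency(g)
    return SpectralSummary(standard_spectrum_adj(adj), normalized_spectrum_adj(adj))


def interlacing_holds(
    mu_g: np.ndarray,
    lam_g: np.ndarray,
    mu_h: np.ndarray,
    lam_h: np.ndarray,
    tol: float = 1e-9,
) -> tuple[bool, bool]:
    """Interlacing verdicts given parent (G) and child (G-e) spectra."""
    n = len(mu_g)
    std_ok = all(
        mu_g[i - 1] - tol <= mu_h[i] <= mu_g[i] + tol for i in range(1, n)
    )
    norm_ok = all(
        lam_g[i - 1] - tol <= lam_h[i] <= lam_g[i + 1] + tol for i in range(1, n - 1)
    )
    return std_ok, norm_ok


def interlacing_check(g: nx.Graph, edge, tol: float = 1e-9) -> tuple[bool, bool]:
    """Check both interlacing theorems for the removal of one edge of g."""
    i, j = edge
    if not g.has_edge(i, j):
        raise ValueError(f"edge {edge!r} not present")
    h = g.copy()
    h.remove_edge(i, j)
    sg, sh = spectral_summary(g), spectral_summary(h)
    return interlacing_holds(sg.mu, sg.lam, sh.mu, sh.lam, tol=tol)


def default_sigma(n: int) -> float:
    """Gaussian kernel width sigma = 1/(3N)."""
    return 1.0 / (3.0 * n)


def spectral_density(
    spectrum: Sequence[float],
    sigma: float | None = None,
    grid: np.ndarray | None = None,
) -> SpectralDensity:
    """Smoothed spectral density phi(x) = (1/N) sum_i N(x; lambda_i, sigma^2)."""
    lam = np.asarray(spectrum, dtype=float)
    if sigma is None:
        sigma = default_sigma(len(lam))
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    z = (x[:, None] - lam[None, :]) / sigma
    vals = np.exp(-0.5 * z**2).sum(axis=1) / (len(lam) * sigma * np.sqrt(2 * np.pi))
    return SpectralDensity(x, vals, float(sigma))


def density_distance(d1: SpectralDensity, d2: SpectralDensity) -> float:
    """L1 distance between two densities sharing a grid (trapezoidal rule)."""
    if d1.grid.shape != d2.grid.shape or not np.allclose(d1.grid, d2.grid):
        raise ValueError("densities must share a grid")
    return float(np.trapezoid(np.abs(d1.values - d2.values), d1.grid))


def spectral_distance(
    g: nx.Graph,
    g2: nx.Graph,
    which: str = "normalized",
    sigma: float | None = None,
    grid: np.ndarray | None = None,
) -> float:
    """Pseudometric d(G, G') = integral of |phi_G - phi_G'|.

    The normalized variant integrates over [0, 2]; the standard variant uses a
    grid spanning [0, 2 * max degree] (an upper bound on mu_N), with the same
    sigma = 1/(3N) convention unless overridden.
    """
    a1, a2 = adjacency(g), adjacency(g2)
    if which == "normalized":
        s1, s2 = normalized_spectrum_adj(a1), normalized_spectrum_adj(a2)
        x = DEFAULT_GRID if grid is None else grid
    elif which == "standard":
        s1, s2 = standard_spectrum_adj(a1), standard_spectrum_adj(a2)
        if grid is None:
            hi = 2.0 * max(a1.sum(axis=1).max(), a2.sum(axis=1).max())
            x = np.linspace(0.0, hi, 2001)
        else:
            x = grid
    else:
        raise ValueError("which must be 'normalized' or 'standard'")
    d1 = spectral_density(s1, sigma=sigma, grid=x)
    d2 = spectral_density(s2, sigma=sigma, grid=x)
    return density_distance(d1, d2)


def ensemble_density(
    members: Iterable,
    sigma: float | None = None,
    grid: np.ndarray | None = None,
) -> SpectralDensity:
    """Mean density of a non-empty set of graphs (or precomputed spectra).

    Each member gets its own sigma = 1/(3N) unless a common sigma is given.
    """
    x = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    total = None
    count = 0
    sig = sigma
    for m in members:
        spec = normalized_spectrum_adj(adjacency(m)) if isinstance(m, nx.Graph) else np.asarray(m)
        d = spectral_density(spec, sigma=sigma, grid=x)
        sig = d.sigma
        total = d.values if total is None else total + d.values
        count += 1
    if count == 0:
        raise ValueError("ensemble_density needs a non-empty set")
    return SpectralDensity(x, total / count, float(sig))
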