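"""Bell-like graph families and their amplification scans.

A bell-like graph joins two identical dense blocks by one or two bridges
(paths of b edges). Block types:

* barbell  B(a,b):   two complete graphs K_a
* dumbbell D(a,b):   two cycles C_a
* moebius  M(a,b):   two Moebius ladders (C_a plus chords i <-> i + a/2, even a)
* antiprism A(a,b):  two antiprisms (circulant C_a(1,2), even a)

With one bridge the order is N = 2a + b - 1 (the bridge has b - 1 interior
degree-2 vertices and one bridgehead per block). Two-bridge variants attach
two vertex-disjoint bridges to adjacent bridgeheads within each block, giving
N = 2a + 2(b - 1). For a = 4 the Moebius ladder and the antiprism both
degenerate to K_4, so M(4,b) and A(4,b) coincide with B(4,b).

One-bridge members with N_eff/N > 1 are weak-selection (and candidate
transient) amplifiers; two-bridge members stay below 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .coalescence import DEFAULT_AMPLIFIER_TOL, effective_population_size

__all__ = ["BellFamilySpec", "make_bell", "bell_order", "scan_family", "smallest_amplifier"]

FAMILIES = ("barbell", "dumbbell", "moebius", "antiprism")


@dataclass(frozen=True)
class BellFamilySpec:
    family: str
    a: int
    b: int
    bridges: int = 1
    bridgehead_offset: int = 1       # two-bridge variants: block distance of the heads
    drop_bridgehead_edge: bool = False

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.bridges not in (1, 2):
            raise ValueError("bridges must be 1 or 2")
        if self.b < 1:
            raise ValueError("need b >= 1 bridge edges")
        if self.family in ("moebius", "antiprism"):
            if self.a < 4 or self.a % 2:
                raise ValueError(f"{self.family} blocks need even a >= 4")
        elif self.a < 3:
            raise ValueError("blocks need a >= 3 vertices")

    @property
    def order(self) -> int:
        return 2 * self.a + self.b - 1 if self.bridges == 1 else 2 * self.a + 2 * (self.b - 1)


def bell_order(family: str, a: int, b: int, bridges: int = 1) -> int:
    return BellFamilySpec(family, a, b, bridges).order


def _block_edges(family: str, a: int, offset: int):
    if family == "barbell":
        return [(offset + i, offset + j) for i in range(a) for j in range(i + 1, a)]
    edges = [(offset + i, offset + (i + 1) % a) for i in range(a)]
    if family == "moebius":
        edges += [(offset + i, offset + i + a // 2) for i in range(a // 2)]
    elif family == "antiprism":
        edges += [(offset + i, offset + (i + 2) % a) for i in range(a)]
    return edges


def make_bell(spec: BellFamilySpec) -> nx.Graph:
    """Construct the bell-like graph described by ``spec``."""
    a, b = spec.a, spec.b
    g = nx.Graph()
    g.add_edges_from(_block_edges(spec.family, a, 0))
    g.add_edges_from(_block_edges(spec.family, a, a))
    nxt = 2 * a

    def bridge(u, v):
        nonlocal nxt
        prev = u
        for _ in range(b - 1):
            g.add_edge(prev, nxt)
            prev = nxt
            nxt += 1
        g.add_edge(prev, v)

    if spec.bridges == 1:
        bridge(0, a)
    else:
        off = spec.bridgehead_offset
        bridge(0, a)
        bridge(off, a + off)
        if spec.drop_bridgehead_edge:
            g.remove_edge(0, off)
            g.remove_edge(a, a + off)
    # antiprism/moebius duplicate a few block edges for tiny a; nx.Graph keeps them simple
    g.graph["label"] = (
        f"{spec.family[0].upper()}{'' if spec.bridges == 1 else '2'}({a},{b})"
    )
    assert g.number_of_nodes() == spec.order
    assert nx.is_connected(g)
    return g


def scan_family(
    family: str,
    bridges: int,
    a_values: Iterable[int],
    b_values: Iterable[int],
) -> pd.DataFrame:
    """N_eff and N_eff/N for every (a, b) in the box; one row per member."""
    rows = []
    for a in a_values:
        for b in b_values:
            spec = BellFamilySpec(family, a, b, bridges)
            n_eff, _ = effective_population_size(make_bell(spec))
            rows.append(
                {"a": a, "b": b, "N": spec.order, "n_eff": n_eff, "ratio": n_eff / spec.order}
            )
    return pd.DataFrame(rows)


def smallest_amplifier(
    family: str,
    bridges: int = 1,
    a_max: int = 12,
    b_max: int = 40,
    tol: float = DEFAULT_AMPLIFIER_TOL,
) -> list[tuple[int, int, int]]:
    """All (a, b, N) attaining the minimal order N with N_eff > N in the box.

    Members are visited in ascending order of N, so the scan stops as soon as
    the minimal amplifying order is complete. Empty list (with a warning) if
    the box contains no amplifier.
    """
    a_min = 4 if family in ("moebius", "antiprism") else 3
    a_step = 2 if family in ("moebius", "antiprism") else 1
    combos: dict[int, list[tuple[int, int]]] = {}
    for a in range(a_min, a_max + 1, a_step):
        for b in range(1, b_max + 1):
            combos.setdefault(BellFamilySpec(family, a, b, bridges).order, []).append((a, b))

    for order in sorted(combos):
        hits = []
        for a, b in sorted(combos[order]):
            g = make_bell(BellFamilySpec(family, a, b, bridges))
            n_eff, _ = effective_population_size(g)
            if n_eff - order > tol:
                hits.append((a, b, order))
        if hits:
            return hits
    warnings.warn(
        f"no amplifying {family} ({bridges} bridge) in a <= {a_max}, b <= {b_max}",
        stacklevel=2,
    )
    return []
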