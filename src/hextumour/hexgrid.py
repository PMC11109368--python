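"""Axial-coordinate hexagonal lattice: geometry, occupancy and spatial weights.

The lattice uses axial coordinates ``(q, r)`` on a hexagon-shaped canvas
centred at the origin.  Every site has exactly six direct neighbours, which
is the interaction neighbourhood for division, clone contact, immune attack
and the binary spatial-weights matrix used by the geostatistics.
"""

from __future__ import annotations

from typing import Iterator, NamedTuple, Optional, Sequence

import numpy as np
from scipy import sparse


class HexCoord(NamedTuple):
    """Axial hex coordinate (column ``q``, row ``r``)."""

    q: int
    r: int


#: The six axial neighbour offsets, in the fixed order used everywhere.
AXIAL_OFFSETS: tuple[tuple[int, int], ...] = (
    (1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1),
)


def neighbours(c: HexCoord | tuple[int, int]) -> tuple[HexCoord, ...]:
    """The six direct neighbours of ``c``, in ``AXIAL_OFFSETS`` order."""
    q, r = c
    return tuple(HexCoord(q + dq, r + dr) for dq, dr in AXIAL_OFFSETS)


def hex_distance(a: HexCoord | tuple[int, int], b: HexCoord | tuple[int, int]) -> int:
    """Minimal number of neighbour steps between two sites.

    Equals ``(|dq| + |dr| + |dq + dr|) / 2`` in axial coordinates.
    """
    dq = a[0] - b[0]
    dr = a[1] - b[1]
    return (abs(dq) + abs(dr) + abs(dq + dr)) // 2


def frac_hex_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Hex metric extended to fractional points (used for centroid seeking)."""
    dq = a[0] - b[0]
    dr = a[1] - b[1]
    return (abs(dq) + abs(dr) + abs(dq + dr)) / 2.0


class HexCanvas:
    """Bounded hexagonal canvas with single-occupancy bookkeeping.

    The canvas holds every coordinate within ``radius`` neighbour steps of the
    origin; the number of sites is ``3·R·(R+1) + 1``.  At most one agent may
    occupy a site; violations raise immediately (the occupancy audit).
    """

    def __init__(self, radius: int):
        if radius < 1:
            raise ValueError("canvas radius must be >= 1")
        self.radius = int(radius)
        self.centre = HexCoord(0, 0)
        self._occ: dict[HexCoord, int] = {}

    @property
    def n_sites(self) -> int:
        return 3 * self.radius * (self.radius + 1) + 1

    @property
    def occupancy(self) -> dict[HexCoord, int]:
        """Read-only view of the occupancy map (coord -> agent id)."""
        return self._occ

    def sites(self) -> Iterator[HexCoord]:
        """All canvas sites, in deterministic (q, r) order."""
        R = self.radius
        for q in range(-R, R + 1):
            for r in range(max(-R, -q - R), min(R, -q + R) + 1):
                yield HexCoord(q, r)

    def in_bounds(self, c: HexCoord | tuple[int, int]) -> bool:
        return hex_distance(c, self.centre) <= self.radius

    def occupant(self, c: HexCoord | tuple[int, int]) -> Optional[int]:
        return self._occ.get(HexCoord(*c))

    def is_empty(self, c: HexCoord | tuple[int, int]) -> bool:
        """True if ``c`` is on the canvas and unoccupied."""
        c = HexCoord(*c)
        return self.in_bounds(c) and c not in self._occ

    def place(self, c: HexCoord | tuple[int, int], agent_id: int) -> None:
        c = HexCoord(*c)
        if not self.in_bounds(c):
            raise ValueError(f"site {c} is outside the canvas (radius {self.radius})")
        if c in self._occ:
            raise ValueError(f"site {c} already occupied by agent {self._occ[c]}")
        self._occ[c] = agent_id

    def remove(self, c: HexCoord | tuple[int, int]) -> int:
        c = HexCoord(*c)
        try:
            return self._occ.pop(c)
        except KeyError:
            raise ValueError(f"site {c} is not occupied") from None

    def move(self, src: HexCoord | tuple[int, int], dst: HexCoord | tuple[int, int]) -> None:
        agent_id = self.remove(src)
        try:
            self.place(dst, agent_id)
        except ValueError:
            self._occ[HexCoord(*src)] = agent_id  # restore before propagating
            raise

    def empty_neighbours(self, c: HexCoord | tuple[int, int]) -> list[HexCoord]:
        return [n for n in neighbours(c) if self.is_empty(n)]


def ring_sites(canvas: HexCanvas, radius: int) -> list[HexCoord]:
    """All sites at hex distance exactly ``radius`` from the canvas centre.

    There are ``6·radius`` of them.  Used to seed the encircling perimeter of
    immune cells.
    """
    if not 0 < radius <= canvas.radius:
        raise ValueError(
            f"ring radius must be in 1..{canvas.radius}, got {radius}"
        )
    out = []
    for q in range(-radius, radius + 1):
        for r in range(max(-radius, -q - radius), min(radius, -q + radius) + 1):
            c = HexCoord(q, r)
            if hex_distance(c, canvas.centre) == radius:
                out.append(c)
    return out


def nearest_empty_toward_centre(
    canvas: HexCanvas,
    from_coord: HexCoord | tuple[int, int],
    rng: np.random.Generator,
) -> Optional[HexCoord]:
    """Empty neighbour of ``from_coord`` closest to the canvas centre.

    Ties are broken uniformly at random from ``rng``.  Returns ``None`` when
    every neighbour is occupied or off-canvas — the "no space to divide"
    signal.
    """
    empties = canvas.empty_neighbours(from_coord)
    if not empties:
        return None
    dists = [hex_distance(e, canvas.centre) for e in empties]
    best = min(dists)
    cands = [e for e, d in zip(empties, dists) if d == best]
    if len(cands) == 1:
        return cands[0]
    return cands[int(rng.integers(len(cands)))]


def adjacent_pairs(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Directed index pairs ``(i, j)`` with ``hex_distance(coords[i], coords[j]) == 1``.

    ``coords`` is an ``(n, 2)`` integer array of distinct axial coordinates.
    Vectorised via key encoding + binary search; O(n log n).
    """
    coords = np.asarray(coords, dtype=np.int64)
    n = coords.shape[0]
    if n == 0:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    qmin = coords[:, 0].min()
    rmin = coords[:, 1].min()
    span = int(coords[:, 1].max() - rmin) + 3
    key = (coords[:, 0] - qmin + 1) * span + (coords[:, 1] - rmin + 1)
    order = np.argsort(key)
    skey = key[order]
    if skey.shape[0] != np.unique(skey).shape[0]:
        raise ValueError("duplicate coordinates")
    i_out: list[np.ndarray] = []
    j_out: list[np.ndarray] = []
    for dq, dr in AXIAL_OFFSETS:
        nk = key + dq * span + dr
        pos = np.searchsorted(skey, nk)
        pos_c = np.minimum(pos, n - 1)
        found = skey[pos_c] == nk
        i_out.append(np.flatnonzero(found))
        j_out.append(order[pos_c[found]])
    return np.concatenate(i_out), np.concatenate(j_out)


def adjacency_weights(coords: Sequence[HexCoord] | np.ndarray) -> sparse.csr_matrix:
    """Binary symmetric spatial-weights matrix ``w_ij`` over ``coords``.

    ``w_ij = 1`` iff sites i and j are direct hex neighbours; zero diagonal.
    Raises on duplicate coordinates.
    """
    arr = np.asarray([(c[0], c[1]) for c in coords], dtype=np.int64).reshape(-1, 2)
    n = arr.shape[0]
    i, j = adjacent_pairs(arr)
    w = sparse.coo_matrix(
        (np.ones(len(i), dtype=float), (i, j)), shape=(n, n)
    ).tocsr()
    return w
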