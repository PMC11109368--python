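"""Global lattice geostatistics of the oncoprotein field.

Three classical global statistics summarise the spatial arrangement of
oncoprotein expression over the occupied cancer-cell sites at every step:

* **Getis-Ord general G** — clustering of high values; in ``[0, 1]`` for
  binary weights (0: high values isolated, 1: all cross product on
  neighbouring pairs).
* **Moran's I** — global spatial autocorrelation; positive for clustering,
  negative for dispersion (idealised range ``[-1, 1]``).
* **Geary's C** — dissimilarity-based autocorrelation; near 0 for perfect
  clustering, 1 under spatial randomness, unbounded above for dispersion.

All three use the binary 6-neighbour adjacency weights from
:func:`hextumour.hexgrid.adjacency_weights` without row standardisation.
Statistics that are undefined (fewer than two sites, zero variance, no
adjacent pairs, zero cross product) raise :class:`UndefinedStatistic`;
the per-step recorder converts that into an explicit NaN marker, never a
silent zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import sparse

from .hexgrid import HexCoord, adjacency_weights


class UndefinedStatistic(ArithmeticError):
    """The requested spatial statistic is not defined for this field."""


@dataclass
class SpatialField:
    """Values observed at distinct lattice sites plus their adjacency weights."""

    coords: np.ndarray            # (n, 2) int axial coordinates
    values: np.ndarray            # (n,) float
    weights: sparse.spmatrix      # (n, n) binary symmetric, zero diagonal

    @classmethod
    def from_coords(
        cls,
        coords: Sequence[HexCoord] | np.ndarray,
        values: Sequence[float] | np.ndarray,
    ) -> "SpatialField":
        arr = np.asarray([(c[0], c[1]) for c in coords], dtype=np.int64).reshape(-1, 2)
        vals = np.asarray(values, dtype=float)
        if arr.shape[0] != vals.shape[0]:
            raise ValueError("coords and values must have the same length")
        return cls(coords=arr, values=vals, weights=adjacency_weights(arr))

    @property
    def n(self) -> int:
        return int(self.values.shape[0])


def general_G(field: SpatialField) -> float:
    """Getis-Ord general G: ``Σ_{i≠j} w_ij x_i x_j / Σ_{i≠j} x_i x_j``."""
    x = field.values
    if field.n < 2:
        raise UndefinedStatistic("general G needs at least two sites")
    if np.any(x < 0):
        raise ValueError("general G requires non-negative values")
    den = float(x.sum() ** 2 - (x ** 2).sum())   # Σ_{i≠j} x_i x_j
    if den <= 0.0:
        raise UndefinedStatistic("general G undefined: zero cross product")
    num = float(x @ (field.weights @ x))
    return num / den


def moran_I(field: SpatialField) -> float:
    """Moran's I: ``(n/S0) · Σ w_ij z_i z_j / Σ z_i²`` with ``z = x − x̄``."""
    x = field.values
    n = field.n
    if n < 2:
        raise UndefinedStatistic("Moran's I needs at least two sites")
    s0 = float(field.weights.sum())
    if s0 == 0.0:
        raise UndefinedStatistic("Moran's I undefined: no adjacent pairs")
    z = x - x.mean()
    den = float(z @ z)
    if den == 0.0:
        raise UndefinedStatistic("Moran's I undefined: zero variance")
    num = float(z @ (field.weights @ z))
    return (n / s0) * (num / den)


def geary_C(field: SpatialField) -> float:
    """Geary's C: ``((n−1)/(2 S0)) · Σ w_ij (x_i − x_j)² / Σ z_i²``."""
    x = field.values
    n = field.n
    if n < 2:
        raise UndefinedStatistic("Geary's C needs at least two sites")
    s0 = float(field.weights.sum())
    if s0 == 0.0:
        raise UndefinedStatistic("Geary's C undefined: no adjacent pairs")
    z = x - x.mean()
    den = float(z @ z)
    if den == 0.0:
        raise UndefinedStatistic("Geary's C undefined: zero variance")
    # Σ_ij w_ij (x_i − x_j)² = 2 Σ_i deg_i x_i² − 2 x' W x  for symmetric binary W
    deg = np.asarray(field.weights.sum(axis=1)).ravel()
    num = 2.0 * float(deg @ (x ** 2)) - 2.0 * float(x @ (field.weights @ x))
    return ((n - 1) / (2.0 * s0)) * (num / den)


@dataclass
class StepRecord:
    """Per-step observables of one simulation run.

    Undefined statistics are stored as NaN.  ``delta_N`` is
    ``N_t − N_{t−1}`` (0 by convention at step 0) and satisfies
    ``delta_N = births − deaths − immune_kills`` exactly.
    """

    step: int
    n_cancer: int
    delta_N: int
    general_G: float
    moran_I: float
    geary_C: float
    n_mutualistic_advantaged: int
    n_clone1: int = 0
    n_clone2: int = 0
    n_boosted: int = 0
    n_immune_active: int = 0
    n_births: int = 0
    n_deaths: int = 0
    n_kills: int = 0
    n_mutualism_events: int = 0


def _safe(fn, field: Optional[SpatialField]) -> float:
    if field is None:
        return math.nan
    try:
        return fn(field)
    except UndefinedStatistic:
        return math.nan


def record_step_statistics(state) -> StepRecord:
    """Build the :class:`StepRecord` for the current model state.

    Works on any object exposing ``config``, ``cancers`` (id -> cell agent),
    ``immunes``, ``step``, ``history`` and per-step counters; the simulation
    engine passes its ``ModelState``.  The field covers cancer-kind cells
    only (stem cells included, immune agents excluded — immune agents carry
    no oncoprotein).
    """
    cfg = state.config
    cells = list(state.cancers.values())
    n = len(cells)
    field_: Optional[SpatialField] = None
    if n >= 2:
        coords = np.fromiter(
            (v for c in cells for v in c.position), dtype=np.int64, count=2 * n
        ).reshape(n, 2)
        values = np.fromiter((c.oncoprotein for c in cells), dtype=float, count=n)
        field_ = SpatialField(coords=coords, values=values,
                              weights=adjacency_weights(coords))
    thr = cfg.oncoprotein_advantage_threshold
    n_boosted = sum(1 for c in cells if c.boost_consumed)
    n_adv = sum(1 for c in cells if c.boost_consumed and c.oncoprotein > thr)
    prev_n = state.history[-1].n_cancer if state.history else n
    return StepRecord(
        step=state.step,
        n_cancer=n,
        delta_N=n - prev_n,
        general_G=_safe(general_G, field_),
        moran_I=_safe(moran_I, field_),
        geary_C=_safe(geary_C, field_),
        n_mutualistic_advantaged=n_adv,
        n_clone1=sum(1 for c in cells if c.clone == 1),
        n_clone2=sum(1 for c in cells if c.clone == 2),
        n_boosted=n_boosted,
        n_immune_active=sum(1 for im in state.immunes.values() if im.active),
        n_births=state.counters.get("births", 0),
        n_deaths=state.counters.get("deaths", 0),
        n_kills=state.counters.get("kills", 0),
        n_mutualism_events=state.counters.get("mutualism_events", 0),
    )
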