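"""Per-step simulation engine: agents, initialisation and phase ordering.

The model is a discrete-time cellular automaton on a hexagonal lattice.
Each step (one hour by default) executes a fixed phase order:

1. immune activation check (tumour size threshold),
2. immune kill (immune agents already holding a target),
3. immune movement (active, unattached agents drift toward the cancer
   centroid),
4. immune targeting (new attachments),
5. spontaneous cancer death,
6. cancer division (daughter placed on the empty neighbour closest to the
   canvas centre),
7. mutualism contact resolution (or random-mutualism assignment),
8. recording of the step statistics.

Targeting and killing deliberately occur in different steps: an immune cell
that attaches at step *t* can kill no earlier than step *t+1* because the
kill phase precedes the targeting phase.

Randomness is drawn from per-phase child streams spawned from the scenario
seed, so toggling one ecological behaviour does not perturb the draws of the
others; a (config, seed) pair fully determines the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Iterable, Optional

import numpy as np

from .config import ConfigurationError, ScenarioConfig
from .geostats import StepRecord, record_step_statistics
from .hexgrid import (
    HexCanvas,
    HexCoord,
    hex_distance,
    nearest_empty_toward_centre,
    neighbours,
    ring_sites,
)

CANCER = "cancer"
STEM = "cancer_stem"

#: Per-phase RNG stream names, in spawn order (fixed; do not reorder).
STREAMS = (
    "init",
    "oncoprotein",
    "death",
    "division",
    "mutualism",
    "random_mutualism",
    "immune_move",
    "immune_target",
    "immune_kill",
)


class CellAgent:
    """A cancer cell or cancer stem cell on the lattice.

    ``effective_division_rate`` equals the base rate until the one-time
    mutualism boost is consumed, after which it is exactly
    ``mutualism_boost × base`` — the boost never compounds.
    """

    __slots__ = ("id", "kind", "clone", "position", "oncoprotein",
                 "base_division_rate", "death_rate", "boost_consumed",
                 "effective_division_rate", "targeted_by")

    def __init__(self, id: int, kind: str, clone: int, position: HexCoord,
                 oncoprotein: float, base_division_rate: float,
                 death_rate: float):
        if kind not in (CANCER, STEM):
            raise ValueError(f"unknown cell kind {kind!r}")
        if oncoprotein < 0:
            raise ValueError("oncoprotein must be >= 0")
        self.id = id
        self.kind = kind
        self.clone = clone
        self.position = HexCoord(*position)
        self.oncoprotein = float(oncoprotein)
        self.base_division_rate = float(base_division_rate)
        self.death_rate = float(death_rate)
        self.boost_consumed = False
        self.effective_division_rate = float(base_division_rate)
        self.targeted_by: Optional[int] = None


class ImmuneAgent:
    """An immune cell: inactive until activation, then seek/target/kill."""

    __slots__ = ("id", "position", "active", "target", "target_step")

    def __init__(self, id: int, position: HexCoord):
        self.id = id
        self.position = HexCoord(*position)
        self.active = False
        self.target: Optional[int] = None
        self.target_step: Optional[int] = None


@dataclass
class ModelState:
    """Full mutable simulation state; agents and canvas occupancy agree."""

    config: ScenarioConfig
    canvas: HexCanvas
    cancers: dict[int, CellAgent]
    immunes: dict[int, ImmuneAgent]
    streams: dict[str, np.random.Generator]
    step: int = 0
    next_id: int = 0
    activated: bool = False
    activation_step: Optional[int] = None
    first_contact_step: Optional[int] = None
    history: list[StepRecord] = dataclass_field(default_factory=list)
    events: list[tuple] = dataclass_field(default_factory=list)
    counters: dict[str, int] = dataclass_field(default_factory=dict)

    def new_id(self) -> int:
        self.next_id += 1
        return self.next_id

    def log(self, event_type: str, agent_a, agent_b, position) -> None:
        q, r = (position[0], position[1]) if position is not None else (None, None)
        self.events.append((self.step, event_type, agent_a, agent_b, q, r))

    def n_cancer(self) -> int:
        return len(self.cancers)

    def audit(self) -> None:
        """Check the canvas/agent bijection and occupancy uniqueness."""
        occ = self.canvas.occupancy
        agents = {**self.cancers, **self.immunes}
        assert len(occ) == len(agents), "occupancy/agent count mismatch"
        for aid, agent in agents.items():
            assert occ.get(agent.position) == aid, f"agent {aid} off its site"


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """One draw from N(mean, sd) truncated at zero (rejection sampling)."""
    if sd == 0.0:
        return max(0.0, mean)
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v >= 0.0:
            return float(v)
    return abs(float(v))


def sample_oncoprotein_field(
    positions: Iterable[HexCoord],
    rng: np.random.Generator,
    n_sweeps: int,
    mean: float = 3.0,
    sd: float = 1.5,
) -> dict[HexCoord, float]:
    """Spatially autocorrelated oncoprotein initialisation.

    MCMC (Gibbs-style) sweeps over the occupied positions: each site's value
    is redrawn from a normal law centred on the mean oncoprotein of its
    already-assigned occupied neighbours (the global prior ``N(mean, sd)``
    when it has none), truncated at zero.  Neighbouring cells therefore end
    up with correlated expression, mimicking the spatial coherence of
    expression observed in real tissue.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    pos_list = [HexCoord(*p) for p in positions]
    pos_set = set(pos_list)
    if len(pos_set) != len(pos_list):
        raise ValueError("positions must be distinct")
    values: dict[HexCoord, float] = {}
    for _ in range(n_sweeps):
        for p in pos_list:
            neigh = [values[nb] for nb in neighbours(p)
                     if nb in pos_set and nb in values]
            centre = float(np.mean(neigh)) if neigh else mean
            values[p] = _truncated_normal(rng, centre, sd)
    return values


def _cluster_sites(canvas: HexCanvas, centre: HexCoord, n: int) -> list[HexCoord]:
    """The ``n`` canvas sites closest to ``centre`` (compact blob), sorted
    deterministically by (distance, q, r)."""
    if n == 0:
        return []
    grow = 1
    while True:
        cand = [c for c in canvas.sites()
                if hex_distance(c, centre) <= grow]
        if len(cand) >= n:
            cand.sort(key=lambda c: (hex_distance(c, centre), c.q, c.r))
            return cand[:n]
        grow += 1
        if grow > 2 * canvas.radius:
            raise ConfigurationError(
                "n_cancer_per_clone: clone does not fit on the canvas")


def initialize_model(config: ScenarioConfig) -> ModelState:
    """Seed two clone clusters (cancer + stem cells) and, with predation, an
    encircling ring of inactive immune cells; sample the oncoprotein field."""
    canvas = HexCanvas(config.canvas_radius)
    ss = np.random.SeedSequence(config.seed)
    streams = {name: np.random.default_rng(child)
               for name, child in zip(STREAMS, ss.spawn(len(STREAMS)))}
    state = ModelState(config=config, canvas=canvas, cancers={}, immunes={},
                       streams=streams)

    sep = config.clone_separation
    centre1 = HexCoord(-((sep + 1) // 2), 0)
    centre2 = HexCoord(sep // 2, 0)
    n_per_clone = config.n_cancer_per_clone + config.n_stem_per_clone
    sites1 = _cluster_sites(canvas, centre1, n_per_clone)
    sites2 = _cluster_sites(canvas, centre2, n_per_clone)
    if set(sites1) & set(sites2):
        raise ConfigurationError(
            "clone_separation: clone seed clusters overlap")

    ring: list[HexCoord] = []
    if config.predation_enabled:
        ring = ring_sites(canvas, config.immune_ring_radius)
        if set(ring) & (set(sites1) | set(sites2)):
            raise ConfigurationError(
                "immune_ring_radius: immune ring intersects the clone seeds")

    init_rng = streams["init"]
    onco = sample_oncoprotein_field(
        sites1 + sites2, streams["oncoprotein"], config.oncoprotein_sweeps,
        mean=config.oncoprotein_mean, sd=config.oncoprotein_sd)

    for clone, sites in ((1, sites1), (2, sites2)):
        n_stem = config.n_stem_per_clone
        stem_idx: set[int] = set()
        if n_stem:
            stem_idx = set(init_rng.choice(len(sites), size=n_stem,
                                           replace=False).tolist())
        for i, site in enumerate(sites):
            cell = CellAgent(
                id=state.new_id(),
                kind=STEM if i in stem_idx else CANCER,
                clone=clone,
                position=site,
                oncoprotein=onco[site],
                base_division_rate=config.division_rate,
                death_rate=config.death_rate,
            )
            state.cancers[cell.id] = cell
            canvas.place(site, cell.id)

    for site in ring:
        imm = ImmuneAgent(id=state.new_id(), position=site)
        state.immunes[imm.id] = imm
        canvas.place(site, imm.id)

    state.history.append(record_step_statistics(state))
    return state


def attempt_division(state: ModelState, cell: CellAgent,
                     u: Optional[float] = None) -> Optional[CellAgent]:
    """One division attempt: Bernoulli(effective rate × dt), then local
    placement toward the canvas centre; forfeited when no neighbour is free.

    Returns the daughter cell, or ``None``.  ``u`` is the pre-drawn uniform
    used by the vectorised phase loop; when omitted a fresh draw is taken
    from the division stream.
    """
    cfg = state.config
    rng = state.streams["division"]
    if u is None:
        u = float(rng.random())
    p = cell.effective_division_rate * cfg.dt
    if u >= p:
        return None
    site = nearest_empty_toward_centre(state.canvas, cell.position, rng)
    if site is None:
        return None
    if cell.kind == STEM:
        kind = STEM if rng.random() < cfg.p_symmetric_division else CANCER
    else:
        kind = CANCER
    onco = max(0.0, cell.oncoprotein + rng.normal(0.0, cfg.oncoprotein_noise_sd))
    daughter = CellAgent(
        id=state.new_id(), kind=kind, clone=cell.clone, position=site,
        oncoprotein=onco, base_division_rate=cell.base_division_rate,
        death_rate=cell.death_rate,
    )
    state.cancers[daughter.id] = daughter
    state.canvas.place(site, daughter.id)
    state.counters["births"] = state.counters.get("births", 0) + 1
    state.log("birth", cell.id, daughter.id, site)
    return daughter


def attempt_death(state: ModelState, cell: CellAgent,
                  u: Optional[float] = None) -> bool:
    """Spontaneous death attempt: Bernoulli(death rate × dt); frees the site."""
    if u is None:
        u = float(state.streams["death"].random())
    if u >= cell.death_rate * state.config.dt:
        return False
    remove_cancer_cell(state, cell)
    state.counters["deaths"] = state.counters.get("deaths", 0) + 1
    state.log("death", cell.id, None, cell.position)
    return True


def remove_cancer_cell(state: ModelState, cell: CellAgent) -> None:
    state.canvas.remove(cell.position)
    del state.cancers[cell.id]


def _shuffled(values, rng: np.random.Generator) -> list:
    order = rng.permutation(len(values))
    return [values[i] for i in order]


def step(state: ModelState) -> ModelState:
    """Advance the model by one step, executing the fixed phase order."""
    from . import ecology  # late import: ecology operates on ModelState

    cfg = state.config
    state.step += 1
    state.counters = {}

    if cfg.predation_enabled:
        ecology.check_activation(state)
        if state.activated:
            kill_rng = state.streams["immune_kill"]
            for imm in _shuffled([im for im in state.immunes.values()
                                  if im.target is not None], kill_rng):
                ecology.immune_kill(state, imm)
            move_rng = state.streams["immune_move"]
            centroid = ecology.cancer_centroid(state)
            for imm in _shuffled([im for im in state.immunes.values()
                                  if im.active and im.target is None],
                                 move_rng):
                ecology.immune_move(state, imm, centroid=centroid)
            target_rng = state.streams["immune_target"]
            for imm in _shuffled([im for im in state.immunes.values()
                                  if im.active and im.target is None],
                                 target_rng):
                ecology.immune_target(state, imm)

    death_rng = state.streams["death"]
    mortal = _shuffled([c for c in state.cancers.values() if c.kind == CANCER],
                       death_rng)
    if mortal:
        us = death_rng.random(len(mortal))
        for cell, u in zip(mortal, us):
            attempt_death(state, cell, u=float(u))

    div_rng = state.streams["division"]
    dividers = _shuffled(list(state.cancers.values()), div_rng)
    if dividers:
        us = div_rng.random(len(dividers))
        for cell, u in zip(dividers, us):
            attempt_division(state, cell, u=float(u))

    if cfg.mutualism_enabled:
        ecology.resolve_mutualism_contacts(state)
    elif cfg.random_mutualism:
        ecology.assign_random_mutualism(
            state, cfg.random_mutualism_rate_at(state.step))

    state.history.append(record_step_statistics(state))
    return state


def run_model(config: ScenarioConfig) -> ModelState:
    """Initialise and run a scenario for ``config.max_steps`` steps."""
    state = initialize_model(config)
    for _ in range(config.max_steps):
        step(state)
    return state
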