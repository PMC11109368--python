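"""Ecological interaction rules: clonal mutualism and immune predation.

Contact mutualism: when cancer cells of the two different clones occupy
adjacent lattice sites, each not-yet-boosted member of the pair gains a
one-time fitness benefit — its instantaneous proliferation rate becomes
exactly 1.25× its base rate and its oncoprotein expression is raised.  The
boost never compounds and is applied at most once per cell.

Random mutualism (the null control): instead of requiring clone contact,
each not-yet-mutualistic cancer cell independently converts with a given
per-step probability, optionally following a per-step rate schedule replayed
from a paired contact-mutualism run.

Immune predation: a perimeter of immune cells stays inactive until the
tumour reaches the activation threshold (3000 cancer cells by default); the
activation is global and irreversible.  Active immune cells drift toward the
centroid of the cancer cells, attach to a neighbouring cancer cell with
probability 0.99, and kill an already-held target with probability 0.99.
Targeting and killing occur at different steps, and an immune cell holds at
most one target at a time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .engine import CellAgent, ImmuneAgent, ModelState, remove_cancer_cell
from .hexgrid import HexCoord, adjacent_pairs, frac_hex_distance, neighbours


@dataclass(frozen=True)
class MutualismEvent:
    """One consummated boost: ``cell_a`` (newly boosted) met ``cell_b``."""

    cell_a: int
    cell_b: int
    step: int


def apply_boost(state: ModelState, cell: CellAgent) -> None:
    """Consume the one-time mutualism boost on ``cell`` (idempotent guard
    is the caller's responsibility: only fresh cells are ever passed)."""
    cfg = state.config
    cell.boost_consumed = True
    cell.effective_division_rate = cfg.mutualism_boost * cell.base_division_rate
    cell.oncoprotein *= cfg.oncoprotein_boost


def resolve_mutualism_contacts(state: ModelState) -> list[MutualismEvent]:
    """Boost every not-yet-boosted cancer cell adjacent to the other clone.

    All heterotypic adjacencies are evaluated simultaneously on the
    pre-phase state; boosting is monotone (the boosted set only grows) and
    already-boosted cells are left untouched, so the outcome is independent
    of iteration order.
    """
    cells = list(state.cancers.values())
    n = len(cells)
    if n < 2:
        return []
    coords = np.fromiter((v for c in cells for v in c.position),
                         dtype=np.int64, count=2 * n).reshape(n, 2)
    clones = np.fromiter((c.clone for c in cells), dtype=np.int64, count=n)
    boosted = np.fromiter((c.boost_consumed for c in cells), dtype=bool, count=n)
    i, j = adjacent_pairs(coords)
    if len(i) == 0:
        return []
    sel = (clones[i] != clones[j]) & ~boosted[i]
    if not np.any(sel):
        return []
    events: list[MutualismEvent] = []
    # first heterotypic partner per newly boosted cell, for the event log
    new_i, first_pos = np.unique(i[sel], return_index=True)
    partners = j[sel][first_pos]
    for idx, pidx in zip(new_i, partners):
        cell = cells[idx]
        apply_boost(state, cell)
        ev = MutualismEvent(cell_a=cell.id, cell_b=cells[pidx].id,
                            step=state.step)
        events.append(ev)
        state.log("mutualism", cell.id, cells[pidx].id, cell.position)
    state.counters["mutualism_events"] = (
        state.counters.get("mutualism_events", 0) + len(events))
    if state.first_contact_step is None:
        state.first_contact_step = state.step
    return events


def assign_random_mutualism(state: ModelState, rate: float) -> int:
    """Convert each fresh cancer cell with probability ``rate`` this step."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"random mutualism rate must be in [0, 1], got {rate}")
    fresh = [c for c in state.cancers.values() if not c.boost_consumed]
    if not fresh or rate == 0.0:
        return 0
    rng = state.streams["random_mutualism"]
    us = rng.random(len(fresh))
    count = 0
    for cell, u in zip(fresh, us):
        if u < rate:
            apply_boost(state, cell)
            state.log("random_mutualism", cell.id, None, cell.position)
            count += 1
    state.counters["mutualism_events"] = (
        state.counters.get("mutualism_events", 0) + count)
    if count and state.first_contact_step is None:
        state.first_contact_step = state.step
    return count


def check_activation(state: ModelState) -> bool:
    """Activate every immune cell once the cancer count reaches the
    threshold; irreversible. Returns whether activation happened now."""
    if state.activated:
        return False
    if state.n_cancer() >= state.config.activation_threshold:
        for imm in state.immunes.values():
            imm.active = True
        state.activated = True
        state.activation_step = state.step
        state.log("activation", None, None, None)
        return True
    return False


def cancer_centroid(state: ModelState) -> Optional[tuple[float, float]]:
    """Mean axial coordinate of all cancer cells (None when none alive).

    This is the "weighted centre" toward which active immune cells drift;
    the default weighting is one per cell.
    """
    if not state.cancers:
        return None
    n = len(state.cancers)
    sq = sr = 0.0
    for c in state.cancers.values():
        sq += c.position[0]
        sr += c.position[1]
    return (sq / n, sr / n)


def immune_move(state: ModelState, immune: ImmuneAgent,
                centroid: Optional[tuple[float, float]] = None
                ) -> Optional[HexCoord]:
    """Move one unattached active immune cell toward the cancer centroid.

    Steps onto the empty neighbour that minimises the (fractional) hex
    distance to the centroid, ties broken uniformly at random; stays put if
    no empty neighbour improves on the current distance, or when no cancer
    cells remain.
    """
    if centroid is None:
        centroid = cancer_centroid(state)
    if centroid is None:
        return None
    rng = state.streams["immune_move"]
    empties = state.canvas.empty_neighbours(immune.position)
    if not empties:
        return None
    here = frac_hex_distance(immune.position, centroid)
    dists = [frac_hex_distance(e, centroid) for e in empties]
    best = min(dists)
    if best >= here:
        return None
    cands = [e for e, d in zip(empties, dists) if d == best]
    dst = cands[0] if len(cands) == 1 else cands[int(rng.integers(len(cands)))]
    state.canvas.move(immune.position, dst)
    immune.position = dst
    return dst


def immune_target(state: ModelState, immune: ImmuneAgent) -> Optional[int]:
    """Attach to one uniformly chosen untargeted neighbouring cancer cell
    with the configured target probability; attachment immobilises the
    immune cell until its target dies."""
    if not immune.active or immune.target is not None:
        return None
    cand: list[CellAgent] = []
    for nb in neighbours(immune.position):
        aid = state.canvas.occupant(nb)
        if aid is not None and aid in state.cancers:
            cell = state.cancers[aid]
            if cell.targeted_by is None:
                cand.append(cell)
    if not cand:
        return None
    rng = state.streams["immune_target"]
    if rng.random() >= state.config.target_probability:
        return None
    cell = cand[0] if len(cand) == 1 else cand[int(rng.integers(len(cand)))]
    immune.target = cell.id
    immune.target_step = state.step
    cell.targeted_by = immune.id
    state.counters["targets"] = state.counters.get("targets", 0) + 1
    state.log("target", immune.id, cell.id, cell.position)
    return cell.id


def immune_kill(state: ModelState, immune: ImmuneAgent) -> Optional[int]:
    """Kill the held target with the configured kill probability.

    A target acquired this very step is never killable (the kill phase runs
    before the targeting phase).  If the target already died of other
    causes, the attachment is simply released.  The immune cell survives and
    re-enters the movement/targeting pool at the next step.
    """
    if immune.target is None:
        return None
    target = state.cancers.get(immune.target)
    if target is None:
        immune.target = None
        immune.target_step = None
        return None
    if immune.target_step is not None and immune.target_step >= state.step:
        return None
    rng = state.streams["immune_kill"]
    if rng.random() >= state.config.kill_probability:
        return None
    remove_cancer_cell(state, target)
    state.counters["kills"] = state.counters.get("kills", 0) + 1
    state.log("kill", immune.id, target.id, target.position)
    immune.target = None
    immune.target_step = None
    return target.id
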