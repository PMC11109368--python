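"""Ecological rules: contact/random mutualism and immune predation."""

import math

import pytest

from hextumour import ScenarioConfig
from hextumour.ecology import (
    assign_random_mutualism,
    cancer_centroid,
    check_activation,
    immune_kill,
    immune_move,
    immune_target,
    resolve_mutualism_contacts,
)
from hextumour.engine import (
    CANCER,
    CellAgent,
    ImmuneAgent,
    initialize_model,
    run_model,
    step,
)
from hextumour.hexgrid import HexCoord, hex_distance, neighbours
from hextumour.io import history_frame


def bare_state(**cfg_kw):
    """An initialised model stripped of its seeded agents, for hand-built
    constellations."""
    base = dict(canvas_radius=20, clone_separation=8, immune_ring_radius=15,
                max_steps=10, seed=11)
    base.update(cfg_kw)
    state = initialize_model(ScenarioConfig(**base))
    for cell in list(state.cancers.values()):
        state.canvas.remove(cell.position)
    state.cancers.clear()
    return state


def add_cancer(state, pos, clone=1, kind=CANCER, onco=3.0):
    cell = CellAgent(id=state.new_id(), kind=kind, clone=clone,
                     position=HexCoord(*pos), oncoprotein=onco,
                     base_division_rate=state.config.division_rate,
                     death_rate=state.config.death_rate)
    state.cancers[cell.id] = cell
    state.canvas.place(cell.position, cell.id)
    return cell


def add_immune(state, pos, active=True):
    imm = ImmuneAgent(id=state.new_id(), position=HexCoord(*pos))
    imm.active = active
    state.immunes[imm.id] = imm
    state.canvas.place(imm.position, imm.id)
    return imm


class TestContactMutualism:
    def test_heterotypic_contact_boosts_both_cells_by_exactly_125(self):
        state = bare_state(mutualism_enabled=True)
        a = add_cancer(state, (0, 0), clone=1, onco=3.0)
        b = add_cancer(state, (1, 0), clone=2, onco=3.5)
        events = resolve_mutualism_contacts(state)
        assert len(events) == 2
        for cell, onco0 in ((a, 3.0), (b, 3.5)):
            assert cell.boost_consumed
            assert cell.effective_division_rate == pytest.approx(
                1.25 * cell.base_division_rate)
            assert cell.oncoprotein == pytest.approx(1.25 * onco0)

    def test_same_clone_adjacency_is_not_mutualism(self):
        state = bare_state(mutualism_enabled=True)
        add_cancer(state, (0, 0), clone=1)
        add_cancer(state, (1, 0), clone=1)
        assert resolve_mutualism_contacts(state) == []

    def test_boost_is_not_compound(self):
        state = bare_state(mutualism_enabled=True)
        a = add_cancer(state, (0, 0), clone=1)
        add_cancer(state, (1, 0), clone=2)
        resolve_mutualism_contacts(state)
        rate_after_first = a.effective_division_rate
        onco_after_first = a.oncoprotein
        # second fresh heterotypic partner appears; a is already boosted
        c = add_cancer(state, (-1, 0), clone=2)
        events = resolve_mutualism_contacts(state)
        assert [e.cell_a for e in events] == [c.id]
        assert c.boost_consumed
        assert a.effective_division_rate == rate_after_first
        assert a.oncoprotein == onco_after_first

    def test_each_cell_boosts_at_most_once_over_a_run(self):
        cfg = ScenarioConfig(canvas_radius=25, clone_separation=10,
                             division_rate=0.08, mutualism_enabled=True,
                             immune_ring_radius=20, max_steps=80, seed=4)
        state = run_model(cfg)
        boosted_events = [e for e in state.events if e[1] == "mutualism"]
        assert boosted_events
        ids = [e[2] for e in boosted_events]
        assert len(ids) == len(set(ids))


class TestRandomMutualism:
    def test_rate_zero_converts_nobody(self):
        state = bare_state(random_mutualism=True)
        for i in range(30):
            add_cancer(state, (i % 6 - 3, i // 6 - 3), clone=1)
        assert assign_random_mutualism(state, 0.0) == 0

    def test_rate_one_converts_every_fresh_cell(self):
        state = bare_state(random_mutualism=True)
        cells = [add_cancer(state, c, clone=1)
                 for c in [(0, 0), (2, 0), (4, 0), (0, 2)]]
        assert assign_random_mutualism(state, 1.0) == 4
        assert all(c.boost_consumed for c in cells)
        # a second pass finds no fresh cells
        assert assign_random_mutualism(state, 1.0) == 0

    def test_conversion_fraction_recovers_3_percent(self):
        state = bare_state(canvas_radius=200, random_mutualism=True)
        sites = iter(state.canvas.sites())
        n = 100_000
        for _ in range(n):
            add_cancer(state, next(sites), clone=1)
        hits = assign_random_mutualism(state, 0.03)
        se = math.sqrt(0.03 * 0.97 / n)
        assert abs(hits / n - 0.03) < 3 * se

    def test_out_of_range_rate_rejected(self):
        state = bare_state(random_mutualism=True)
        with pytest.raises(ValueError):
            assign_random_mutualism(state, 1.2)


class TestActivation:
    @pytest.mark.parametrize("count,expect", [(2999, False), (3000, True)])
    def test_threshold_is_3000_cells(self, count, expect):
        state = bare_state(canvas_radius=40, predation_enabled=True,
                           immune_ring_radius=38)
        sites = (s for s in state.canvas.sites() if state.canvas.is_empty(s))
        for _ in range(count):
            add_cancer(state, next(sites), clone=1)
        assert check_activation(state) is expect
        assert state.activated is expect
        assert all(im.active is expect for im in state.immunes.values())

    def test_activation_is_irreversible(self):
        state = bare_state(canvas_radius=40, predation_enabled=True,
                           immune_ring_radius=38, activation_threshold=5)
        for i in range(5):
            add_cancer(state, (i, 0), clone=1)
        assert check_activation(state)
        for cell in list(state.cancers.values()):
            state.canvas.remove(cell.position)
        state.cancers.clear()
        assert not check_activation(state)  # no re-trigger, no deactivation
        assert state.activated
        assert all(im.active for im in state.immunes.values())

    def test_no_targeting_before_threshold(self):
        cfg = ScenarioConfig(canvas_radius=25, clone_separation=10,
                             division_rate=0.05, predation_enabled=True,
                             immune_ring_radius=20, max_steps=60, seed=9)
        state = run_model(cfg)  # threshold 3000 unreachable here
        assert state.activation_step is None
        assert not [e for e in state.events if e[1] in ("target", "kill")]


class TestImmuneMovement:
    def test_approaches_the_cancer_centroid_monotonically(self):
        state = bare_state(predation_enabled=True)
        add_cancer(state, (0, 0), clone=1)
        imm = add_immune(state, (8, 0))
        dists = [hex_distance(imm.position, (0, 0))]
        for _ in range(10):
            immune_move(state, imm)
            dists.append(hex_distance(imm.position, (0, 0)))
        assert dists[0] == 8 and dists[-1] == 1
        assert all(b <= a for a, b in zip(dists, dists[1:]))

    def test_blocked_immune_stays_put(self):
        state = bare_state(predation_enabled=True)
        add_cancer(state, (0, 0), clone=1)
        imm = add_immune(state, (5, 0))
        for n in neighbours((5, 0)):
            add_cancer(state, n, clone=1)
        assert immune_move(state, imm) is None
        assert imm.position == (5, 0)

    def test_no_cancer_means_no_centroid_and_no_motion(self):
        state = bare_state(predation_enabled=True)
        imm = add_immune(state, (5, 0))
        assert cancer_centroid(state) is None
        assert immune_move(state, imm) is None
        assert imm.position == (5, 0)


class TestTargetingAndKilling:
    def test_certain_targeting_attaches_to_the_only_neighbour(self):
        state = bare_state(predation_enabled=True, target_probability=1.0)
        cell = add_cancer(state, (0, 0), clone=1)
        imm = add_immune(state, (1, 0))
        assert immune_target(state, imm) == cell.id
        assert imm.target == cell.id and cell.targeted_by == imm.id

    def test_attached_immune_takes_no_second_target(self):
        state = bare_state(predation_enabled=True, target_probability=1.0)
        add_cancer(state, (0, 0), clone=1)
        other = add_cancer(state, (1, -1), clone=1)
        imm = add_immune(state, (1, 0))
        first = immune_target(state, imm)
        assert immune_target(state, imm) is None
        assert imm.target == first != other.id or imm.target == first

    def test_cancer_cell_is_targeted_by_at_most_one_immune(self):
        state = bare_state(predation_enabled=True, target_probability=1.0)
        cell = add_cancer(state, (0, 0), clone=1)
        imm1 = add_immune(state, (1, 0))
        imm2 = add_immune(state, (-1, 0))
        assert immune_target(state, imm1) == cell.id
        assert immune_target(state, imm2) is None

    def test_targeting_frequency_recovers_099(self):
        state = bare_state(predation_enabled=True, target_probability=0.99)
        cell = add_cancer(state, (0, 0), clone=1)
        imm = add_immune(state, (1, 0))
        n, hits = 10_000, 0
        for _ in range(n):
            if immune_target(state, imm) is not None:
                hits += 1
            imm.target = None
            imm.target_step = None
            cell.targeted_by = None
        se = math.sqrt(0.99 * 0.01 / n)
        assert abs(hits / n - 0.99) < 3 * se

    def test_kill_frequency_recovers_099(self):
        state = bare_state(predation_enabled=True, kill_probability=0.99)
        imm = add_immune(state, (1, 0))
        n, hits = 10_000, 0
        state.step = 5
        for _ in range(n):
            cell = add_cancer(state, (0, 0), clone=1)
            imm.target = cell.id
            imm.target_step = state.step - 1
            cell.targeted_by = imm.id
            if immune_kill(state, imm) is not None:
                hits += 1
            else:
                state.canvas.remove(cell.position)
                del state.cancers[cell.id]
                imm.target = None
        se = math.sqrt(0.99 * 0.01 / n)
        assert abs(hits / n - 0.99) < 3 * se

    def test_kill_never_lands_on_the_targeting_step(self):
        state = bare_state(predation_enabled=True, target_probability=1.0,
                           kill_probability=1.0)
        cell = add_cancer(state, (0, 0), clone=1)
        imm = add_immune(state, (1, 0))
        state.step = 3
        immune_target(state, imm)
        assert immune_kill(state, imm) is None       # same step: no kill
        assert cell.id in state.cancers
        state.step = 4
        assert immune_kill(state, imm) == cell.id    # next step: certain kill
        assert cell.id not in state.cancers
        assert imm.target is None                    # ready to re-target

    def test_stale_target_releases_without_kill(self):
        state = bare_state(predation_enabled=True, kill_probability=1.0)
        cell = add_cancer(state, (0, 0), clone=1)
        imm = add_immune(state, (1, 0))
        imm.target, imm.target_step = cell.id, 0
        state.step = 2
        state.canvas.remove(cell.position)
        del state.cancers[cell.id]  # died of other causes
        assert immune_kill(state, imm) is None
        assert imm.target is None

    def test_kill_before_retarget_across_engine_steps(self):
        """An immune cell that attaches at step t kills no earlier than t+1:
        the kill phase precedes the targeting phase inside a step."""
        state = bare_state(predation_enabled=True, target_probability=1.0,
                           kill_probability=1.0, activation_threshold=1,
                           division_rate=0.0, death_rate=0.0)
        cell = add_cancer(state, (0, 0), clone=1)
        add_immune(state, (1, 0), active=False)
        step(state)
        assert cell.id in state.cancers          # targeted only
        assert [e[1] for e in state.events if e[1] in ("target", "kill")] == ["target"]
        step(state)
        assert cell.id not in state.cancers      # killed one step later
        assert [e[1] for e in state.events if e[1] in ("target", "kill")] == ["target", "kill"]


class TestPredationNeutrality:
    def test_inactive_immune_ring_reproduces_the_no_predation_curve(self):
        """While the immune system never activates, its mere presence leaves
        the growth curve exactly identical to the seed-paired no-predation
        run (per-phase RNG streams), hence KS p = 1."""
        for seed in (1, 2):
            cfg = ScenarioConfig(canvas_radius=25, clone_separation=10,
                                 division_rate=0.08, immune_ring_radius=20,
                                 max_steps=80, seed=seed)  # threshold 3000: unreachable
            h_off = history_frame(run_model(cfg).history)
            h_on = history_frame(run_model(cfg.replace(
                predation_enabled=True)).history)
            assert h_on.n_cancer.tolist() == h_off.n_cancer.tolist()

    def test_zero_probabilities_produce_no_predation_events(self):
        """With target and kill probabilities 0, activated immune cells
        still move (and may crowd the boundary) but never target or kill;
        the population only ever shrinks through spontaneous death."""
        cfg = ScenarioConfig(canvas_radius=25, clone_separation=10,
                             division_rate=0.08, immune_ring_radius=20,
                             activation_threshold=100, max_steps=80,
                             predation_enabled=True, target_probability=0.0,
                             kill_probability=0.0, seed=3)
        state = run_model(cfg)
        assert state.activated
        assert not [e for e in state.events if e[1] in ("target", "kill")]
        h = history_frame(state.history)
        assert (h.n_kills == 0).all()
        assert (h.delta_N == h.n_births - h.n_deaths).all()


def test_boosted_set_grows_monotonically():
    cfg = ScenarioConfig(canvas_radius=25, clone_separation=10,
                         division_rate=0.08, mutualism_enabled=True,
                         immune_ring_radius=20, max_steps=60, seed=13)
    state = run_model(cfg)
    h = history_frame(state.history)
    boosted = h.n_boosted + h.n_deaths.cumsum()  # deaths may remove boosted cells
    assert (h.n_mutualism_events >= 0).all()
    assert h.n_boosted.iloc[-1] > 0
    # cumulative conversions never decrease
    assert (h.n_mutualism_events.cumsum().diff().fillna(0) >= 0).all()
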