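"""Reactive-controller contracts: capture, gating, replay, ramp, bonding."""

import numpy as np
import pytest
from scipy import stats

from redoxfold import fixtures
from redoxfold.controller import (
    Checkpoint,
    SegmentRecord,
    _break_disulfide,
    build_disulfide_restraints,
    detect_capture,
    form_disulfide,
    gate_decision,
    gate_stream,
    maybe_reduce,
    rewind_to_crossing,
    run_oxidative_folding,
    run_ramp,
)
from redoxfold.errors import ConfigError, ReplayError, TopologyError
from redoxfold.forcefield import Propagator, total_energy
from redoxfold.model_core import (
    ControllerConfig,
    Frame,
    RampSchedule,
    ReductionConfig,
    Topology,
    ordered_pair,
)


def _free_sulfurs(n=4):
    """n free reactive sulfur beads (no bonds) for synthetic segments."""
    topo = Topology(
        residue_labels=["RCYS"] * n,
        particle_names=["SG"] * n,
        particle_residue=list(range(n)),
        masses=np.full(n, 32.0),
        reactive_sites=list(range(n)),
    )
    topo.refresh_mask()
    return topo


def _segment(distances_per_frame):
    """Synthetic SegmentRecord: each entry is {(i, j): distance}; all other
    pairs are held far apart."""
    frames = []
    n = 4
    for t, dmap in enumerate(distances_per_frame):
        pos = np.array(
            [[0.0, 0.0, 100.0 * i] for i in range(n)]
        )
        for (i, j), d in dmap.items():
            pos[j] = pos[i] + [d, 0.0, 0.0]
        frames.append(
            Frame(time=float(t + 1), positions=pos, velocities=np.zeros_like(pos))
        )
    start = Frame(time=0.0, positions=np.zeros((n, 3)) + np.arange(n)[:, None],
                  velocities=np.zeros((n, 3)))
    return SegmentRecord(0, start, frames)


class TestDetectCapture:
    def test_no_crossing_returns_none(self):
        topo = _free_sulfurs()
        seg = _segment([{(0, 1): 2.6}] * 10)
        assert detect_capture(seg, topo, 2.5) is None

    def test_earliest_frame_wins(self):
        # pair (0,1) crosses at frame 37; (2,3) crosses deeper but later
        frames = [{}] * 37 + [{(0, 1): 2.4}] * 15 + [{(0, 1): 2.4, (2, 3): 2.3}]
        seg = _segment(frames)
        assert detect_capture(seg, _free_sulfurs(), 2.5) == (37, (0, 1))

    def test_tie_breaks_by_smallest_distance(self):
        frames = [{}] * 10 + [{(0, 1): 2.45, (2, 3): 2.30}]
        seg = _segment(frames)
        assert detect_capture(seg, _free_sulfurs(), 2.5) == (10, (2, 3))

    def test_tie_breaks_by_lowest_pair_on_equal_distance(self):
        frames = [{(0, 1): 2.4, (2, 3): 2.4}]
        seg = _segment(frames)
        assert detect_capture(seg, _free_sulfurs(), 2.5) == (0, (0, 1))

    def test_empty_reactive_set(self):
        topo = _free_sulfurs()
        topo.reactive_sites = []
        topo.refresh_mask()
        assert detect_capture(_segment([{}]), topo, 2.5) is None

    def test_two_bead_fixture_thresholds(self):
        topo, near = fixtures.two_bead_system(2.4)
        _, far = fixtures.two_bead_system(2.6)
        seg_near = SegmentRecord(0, near, [near])
        seg_far = SegmentRecord(0, far, [far])
        assert detect_capture(seg_near, topo, 2.5) == (0, (0, 1))
        assert detect_capture(seg_far, topo, 2.5) is None


class TestGate:
    def test_always_accepts_at_unit_probability(self, rng):
        assert all(gate_decision(rng, 1.0) for _ in range(100))

    def test_invalid_probability(self, rng):
        for bad in (0.0, -0.1, 1.0001):
            with pytest.raises(ConfigError):
                gate_decision(rng, bad)

    def test_acceptance_fraction_at_p0(self):
        # reduced-reactivity default p0 = 0.001, one million decisions
        rng = np.random.default_rng(100)
        n = 1_000_000
        hits = int(gate_stream(rng, 0.001, n).sum())
        se = np.sqrt(0.001 * 0.999 / n)
        assert abs(hits / n - 0.001) < 3 * se

    def test_stream_matches_scalar_decisions(self):
        a = np.random.default_rng(7)
        b = np.random.default_rng(7)
        stream = gate_stream(a, 0.3, 500)
        scalar = np.array([gate_decision(b, 0.3) for _ in range(500)])
        assert np.array_equal(stream, scalar)

    def test_waiting_times_are_geometric(self):
        """Contact frames until acceptance follow a geometric law."""
        p = 0.01
        rng = np.random.default_rng(31)
        draws = gate_stream(rng, p, 600_000)
        idx = np.flatnonzero(draws)
        waits = np.diff(idx)  # rejected frames between acceptances + 1
        assert abs(waits.mean() - 1 / p) / (1 / p) < 0.05
        # chi-square goodness of fit against geometric(p)
        edges = np.array([0, 25, 50, 100, 200, 400, 800, np.inf])
        observed, _ = np.histogram(waits, bins=edges)
        cdf = lambda k: 1 - (1 - p) ** k
        probs = np.diff([cdf(e) if np.isfinite(e) else 1.0 for e in edges])
        expected = probs * len(waits)
        chi2 = ((observed - expected) ** 2 / expected).sum()
        pval = 1 - stats.chi2.cdf(chi2, df=len(observed) - 1)
        assert pval > 0.01


@pytest.fixture(scope="module")
def recorded_segment(guanylin):
    topo, frame = guanylin
    fr = frame.copy()
    fr.rng_state = np.random.default_rng(77).bit_generator.state
    prop = Propagator(topo)
    frames = prop.run(fr, 20 * 500, record_every=500)
    return topo, prop, SegmentRecord(0, fr, frames)


class TestRewind:
    def test_replay_of_last_frame_is_bitwise(self, recorded_segment):
        _, prop, seg = recorded_segment
        got = rewind_to_crossing(seg, len(seg.frames) - 1, prop, 500)
        assert np.array_equal(got.positions, seg.frames[-1].positions)
        assert np.array_equal(got.velocities, seg.frames[-1].velocities)

    def test_replay_of_interior_frame_is_bitwise(self, recorded_segment):
        _, prop, seg = recorded_segment
        got = rewind_to_crossing(seg, 7, prop, 500)
        assert np.array_equal(got.positions, seg.frames[7].positions)

    def test_perturbed_seed_raises_reproducibility_error(self, recorded_segment):
        _, prop, seg = recorded_segment
        bad = SegmentRecord(
            seg.segment_index,
            seg.start_frame.copy(),
            seg.frames,
        )
        bad.start_frame.rng_state = np.random.default_rng(78).bit_generator.state
        with pytest.raises(ReplayError):
            rewind_to_crossing(bad, 7, prop, 500)

    def test_segment_frame_spacing_invariant(self, recorded_segment):
        _, _, seg = recorded_segment
        dt_frame = seg.frames[0].time - seg.start_frame.time
        assert dt_frame == pytest.approx(1.0)
        spacings = np.diff([f.time for f in seg.frames])
        assert np.allclose(spacings, dt_frame)


class TestRamp:
    def test_two_bead_ramp_reaches_target(self):
        topo, frame = fixtures.two_bead_system(2.5)
        cfg = ControllerConfig(seed=5)
        frame.rng_state = np.random.default_rng(5).bit_generator.state
        rs = build_disulfide_restraints(topo, (0, 1), cfg, frame)
        schedule = RampSchedule(n_steps=50, step_duration=1.0)
        final, frames, alphas = run_ramp(
            frame, topo, (0, 1), rs, schedule, cfg, record_every_ps=0.5
        )
        assert alphas[0][1] == pytest.approx(1.0 / 50)
        assert alphas[-1][1] == 1.0
        tail = [f.distance(0, 1) for f in frames[-4:]]
        assert np.mean(tail) == pytest.approx(2.038, abs=0.15)

    def test_ramp_alpha_held_constant_within_window(self):
        sched = RampSchedule(n_steps=4, step_duration=0.5)
        topo, frame = fixtures.two_bead_system(2.5)
        cfg = ControllerConfig(seed=1)
        frame.rng_state = np.random.default_rng(1).bit_generator.state
        rs = build_disulfide_restraints(topo, (0, 1), cfg, frame)
        _, _, alphas = run_ramp(frame, topo, (0, 1), rs, sched, cfg)
        assert [a for _, a in alphas] == [0.25, 0.5, 0.75, 1.0]

    def test_dihedral_target_sign_follows_geometry(self):
        topo, frame = fixtures.four_bead_css_c(dihedral=-85.0)
        cfg = ControllerConfig()
        rs = build_disulfide_restraints(topo, (1, 2), cfg, frame)
        assert rs.dihedrals[0].target == -90.0
        topo2, frame2 = fixtures.four_bead_css_c(dihedral=85.0)
        rs2 = build_disulfide_restraints(topo2, (1, 2), cfg, frame2)
        assert rs2.dihedrals[0].target == 90.0


class TestFormDisulfide:
    def test_bookkeeping_after_both_bonds(self, guanylin):
        topo, _ = guanylin
        cfg = ControllerConfig()
        s = topo.reactive_sites  # sulfurs of residues 4, 7, 12, 15
        t1 = form_disulfide(topo, (s[0], s[2]), cfg)
        t2 = form_disulfide(t1, (s[1], s[3]), cfg)
        assert t2.reactive_sites == []
        assert t2.disulfides == {ordered_pair(s[0], s[2]), ordered_pair(s[1], s[3])}
        assert all(
            t2.residue_labels[t2.particle_residue[x]] == "XCYS"
            for pair in t2.disulfides for x in pair
        )

    def test_mask_entries_involving_bonded_pair_removed(self, guanylin):
        topo, _ = guanylin
        s = topo.reactive_sites
        t1 = form_disulfide(topo, (s[0], s[2]), ControllerConfig())
        for other in (s[1], s[3]):
            assert ordered_pair(s[0], other) not in t1.lj_mask
            assert ordered_pair(s[2], other) not in t1.lj_mask
        assert t1.lj_mask == {ordered_pair(s[1], s[3])}

    def test_handoff_is_energy_neutral(self, guanylin):
        """Restraints at full strength and the installed generic bond give
        the same energy on the same frame."""
        topo, frame = guanylin
        cfg = ControllerConfig()
        s = topo.reactive_sites
        pair = (s[0], s[2])
        fr = frame.copy()
        fr.positions[pair[1]] = fr.positions[pair[0]] + [2.1, 0.4, 0.0]
        rs = build_disulfide_restraints(topo, pair, cfg, fr)
        from redoxfold.controller import ramp_topology

        before = total_energy(fr, ramp_topology(topo, pair), rs, alpha=1.0).total
        bonded = form_disulfide(topo, pair, cfg, rs)
        after = total_energy(fr, bonded).total
        assert after == pytest.approx(before, abs=1e-6)

    def test_double_bonding_is_a_logic_error(self, guanylin):
        topo, _ = guanylin
        cfg = ControllerConfig()
        s = topo.reactive_sites
        t1 = form_disulfide(topo, (s[0], s[2]), cfg)
        with pytest.raises(TopologyError):
            form_disulfide(t1, (s[0], s[1]), cfg)


class TestReduction:
    def _bonded(self, guanylin):
        topo, frame = guanylin
        s = topo.reactive_sites
        return form_disulfide(topo, (s[0], s[2]), ControllerConfig()), frame

    def test_zero_probability_never_reduces(self, guanylin, rng):
        topo, frame = self._bonded(guanylin)
        cfg = ReductionConfig(enabled=True, base_prob=0.0)
        for _ in range(50):
            out, events = maybe_reduce(topo, frame, cfg, rng)
            assert out is topo and not events

    def test_certain_reduction_restores_reactive_state(self, guanylin, rng):
        topo, frame = self._bonded(guanylin)
        pair = next(iter(topo.disulfides))
        out, events = maybe_reduce(
            topo, frame, ReductionConfig(enabled=True, base_prob=1.0), rng
        )
        assert not out.disulfides
        assert sorted(out.reactive_sites) == sorted(
            topo.reactive_sites + list(pair)
        )
        assert events[0].kind == "reduced"

    def test_break_inverts_form_exactly(self, guanylin):
        topo, _ = guanylin
        cfg = ControllerConfig()
        s = topo.reactive_sites
        bonded = form_disulfide(topo, (s[0], s[2]), cfg)
        restored = _break_disulfide(bonded, (s[0], s[2]))
        assert restored.to_dict() == topo.to_dict()

    def test_reduction_rate_matches_base_prob(self, guanylin):
        topo, frame = self._bonded(guanylin)
        cfg = ReductionConfig(enabled=True, base_prob=0.25)
        rng = np.random.default_rng(55)
        n, hits = 400, 0
        for _ in range(n):
            _, events = maybe_reduce(topo, frame, cfg, rng)
            hits += bool(events)
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(hits / n - 0.25) < 3 * se

    def test_buriedness_exposure_bounded(self, guanylin):
        from redoxfold.controller import _exposure

        topo, frame = self._bonded(guanylin)
        pair = next(iter(topo.disulfides))
        e = _exposure(topo, frame, pair, "buriedness")
        assert 0.0 < e <= 1.0


class TestFullRun:
    def test_zero_reactive_sites_matches_conventional_run(self):
        spec = fixtures.ChainSpec(n_residues=8, reactive_positions=(), seed=2)
        topo, frame = fixtures.random_chain(spec)
        cfg = ControllerConfig.desk(
            seed=9, stage_lengths=(10.0, 50.0, 10.0), segment_length=10.0
        )
        res = run_oxidative_folding(topo, frame, cfg)
        # conventional: same dynamics stream, no controller
        ss = np.random.SeedSequence(9)
        dyn = ss.spawn(3)[0]
        fr = frame.copy()
        fr.rng_state = np.random.default_rng(dyn).bit_generator.state
        prop = Propagator(topo)
        conv = prop.run(fr, 20 * 500, record_every=500)
        assert len(res.frames) == len(conv) + 1  # + initial frame
        for a, b in zip(res.frames[1:], conv):
            assert np.array_equal(a.positions, b.positions)

    def test_first_bond_precedes_second(self, folding_ensemble):
        for res in folding_ensemble:
            formed = res.formed
            if len(formed) == 2:
                assert formed[0].trigger_time < formed[1].trigger_time

    def test_every_trigger_within_capture_radius(self, folding_ensemble):
        triggers = [e.trigger_distance for r in folding_ensemble for e in r.formed]
        assert triggers, "no bonds formed across the ensemble"
        assert max(triggers) <= 2.5

    def test_ensemble_mostly_completes(self, folding_ensemble):
        done = sum(r.status == "complete" for r in folding_ensemble)
        assert done >= 10

    def test_event_log_is_time_ordered(self, folding_ensemble):
        for res in folding_ensemble:
            times = [e.trigger_time for e in res.events]
            assert times == sorted(times)

    def test_alpha_history_reaches_unity_per_bond(self, folding_ensemble):
        res = next(r for r in folding_ensemble if r.formed)
        alphas = [a for _, a in res.alpha_history]
        assert alphas.count(1.0) == len(res.formed)

    def test_checkpoint_round_trip(self, guanylin):
        topo, frame = guanylin
        cp = Checkpoint(
            topology=topo, frame=frame, folding_elapsed=100.0, seg_index=3,
            rejected=17,
            gate_state=np.random.default_rng(1).bit_generator.state,
            red_state=np.random.default_rng(2).bit_generator.state,
            events=[], t_fold_start=50.0,
        )
        back = Checkpoint.from_dict(cp.to_dict())
        assert back.to_dict() == cp.to_dict()

    def test_resume_reproduces_uninterrupted_run(self):
        """Folding continued from a segment checkpoint yields the same
        events as the uninterrupted run."""
        topo, frame = fixtures.guanylin_chain(seed=4)
        cfg = ControllerConfig.desk(seed=4, stage_lengths=(20.0, 1500.0, 0.0))
        captured = []
        full = run_oxidative_folding(
            topo, frame, cfg,
            on_segment=lambda cp, seg: captured.append(cp),
        )
        assert captured, "no segments recorded"
        mid = captured[min(2, len(captured) - 1)]
        resumed = run_oxidative_folding(topo, frame, cfg, resume=mid)

        def key(e):
            # trigger_frame indexes each run's own trajectory list, which
            # restarts at the checkpoint; everything physical must agree
            return (e.pair, e.residues, e.trigger_time, e.trigger_distance,
                    e.gate_draws, e.kind)

        tail = [key(e) for e in full.events if e not in mid.events]
        new = [key(e) for e in resumed.events if e not in mid.events]
        assert new == tail
        assert resumed.topology.disulfides == full.topology.disulfides


class TestPerturbationFreeness:
    def test_masked_run_is_bitwise_standard_while_pairs_are_far(self):
        """Over a window where every reactive S–S distance stays above
        3.5 Å, the reactive machinery changes nothing — trajectories with
        and without it are bitwise identical."""
        topo, frame = fixtures.guanylin_chain(seed=21)
        conventional = topo.copy()
        conventional.lj_mask = set()
        fr = frame.copy()
        fr.rng_state = np.random.default_rng(3).bit_generator.state
        # sample every 0.05 ps so the >3.5 Å condition is verified densely
        masked = Propagator(topo).run(fr, 10 * 500, record_every=25)
        plain = Propagator(conventional).run(fr, 10 * 500, record_every=25)
        pairs = topo.reactive_pairs()
        margin = 3.5 + 0.2  # headroom for excursions between samples
        n_checked = 0
        for a, b in zip(masked, plain):
            if min(a.distance(*p) for p in pairs) <= margin:
                break
            assert np.array_equal(a.positions, b.positions)
            assert np.array_equal(a.velocities, b.velocities)
            n_checked += 1
        assert n_checked >= 20, "window too short to be meaningful"
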