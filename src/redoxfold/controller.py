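"""The oxidative-folding controller.

Implements the segmented reactive protocol: the trajectory is advanced in
fixed-length segments under the masked potential; each stored frame is
scanned for reactive sulfur pairs inside the capture radius (2.5 Å); a
stochastic gate with per-contact-frame acceptance probability p0 decides
whether an encounter is productive; on acceptance the segment is rewound
bitwise to the crossing frame, artificial disulfide restraints are ramped
up step-wise (alpha = k/n over 10-ps windows), and the topology is mutated
to carry a permanent disulfide whose bonded terms exactly replace the
fully-ramped restraints.  An optional reverse step reduces formed bonds
with a low probability scaled by a solvent-exposure proxy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, RampFailureError, ReplayError, TopologyError
from .forcefield import Propagator, _dihedral
from .model_core import (
    RCYS,
    XCYS,
    AngleRestraint,
    AngleTerm,
    BondEvent,
    BondTerm,
    ControllerConfig,
    DihedralRestraint,
    DihedralTerm,
    DistanceRestraint,
    Frame,
    RampSchedule,
    ReductionConfig,
    RestraintSet,
    Topology,
    ordered_pair,
)

__all__ = [
    "SegmentRecord",
    "FoldingResult",
    "detect_capture",
    "gate_decision",
    "gate_stream",
    "rewind_to_crossing",
    "build_disulfide_restraints",
    "ramp_topology",
    "run_ramp",
    "form_disulfide",
    "maybe_reduce",
    "run_oxidative_folding",
]


@dataclass
class SegmentRecord:
    """One recorded segment: the restart point and the stored frames.

    ``frames[i]`` lies ``(i + 1) * frame_interval`` after the restart, so
    ``frames[0].time - start_frame.time == frame_interval``.  Replaying
    ``start_frame`` reproduces ``frames`` bitwise.
    """

    segment_index: int
    start_frame: Frame
    frames: list[Frame]


def detect_capture(
    segment: SegmentRecord, topology: Topology, r_c: float
) -> tuple[int, tuple[int, int]] | None:
    """Earliest frame index at which any reactive pair is within ``r_c``.

    Ties within one frame break by smallest distance, then lowest pair.
    Returns None when no crossing occurs (including an empty reactive set).
    """
    pairs = topology.reactive_pairs()
    if not pairs:
        return None
    for n, fr in enumerate(segment.frames):
        best = None
        for pair in pairs:
            d = fr.distance(*pair)
            if d <= r_c:
                key = (d, pair)
                if best is None or key < best:
                    best = key
        if best is not None:
            return n, best[1]
    return None


def gate_decision(rng: np.random.Generator, accept_prob: float) -> bool:
    """One rejection-sampling decision: true iff U(0,1) < accept_prob."""
    if not 0.0 < accept_prob <= 1.0:
        raise ConfigError(f"accept_prob {accept_prob} outside (0, 1]")
    return bool(rng.random() < accept_prob)


def gate_stream(rng: np.random.Generator, accept_prob: float, n: int) -> np.ndarray:
    """Vectorised batch of ``n`` gate decisions (same draw sequence as
    calling :func:`gate_decision` ``n`` times)."""
    if not 0.0 < accept_prob <= 1.0:
        raise ConfigError(f"accept_prob {accept_prob} outside (0, 1]")
    return rng.random(n) < accept_prob


def _scan_with_gate(
    segment: SegmentRecord,
    topology: Topology,
    r_c: float,
    accept_prob: float,
    rng: np.random.Generator,
) -> tuple[int, tuple[int, int], int] | None:
    """Scan a segment frame by frame, gating every contact.

    Returns (frame index, pair, rejected draws within this segment) on
    acceptance, else None (rejected draws are re-counted by the caller).
    """
    pairs = topology.reactive_pairs()
    if not pairs:
        return None
    rejected = 0
    for n, fr in enumerate(segment.frames):
        contacts = sorted(
            ((fr.distance(*p), p) for p in pairs if fr.distance(*p) <= r_c)
        )
        for _d, pair in contacts:
            if gate_decision(rng, accept_prob):
                return n, pair, rejected
            rejected += 1
    return None if rejected == 0 else (-1, (-1, -1), rejected)


def rewind_to_crossing(
    segment: SegmentRecord,
    n: int,
    propagator: Propagator,
    steps_per_frame: int,
) -> Frame:
    """Re-propagate from the segment restart to frame ``n``.

    The returned frame must be bitwise identical to ``segment.frames[n]``;
    any divergence is a fatal reproducibility error.
    """
    frames = propagator.run(
        segment.start_frame,
        (n + 1) * steps_per_frame,
        record_every=steps_per_frame,
    )
    replayed = frames[n]
    stored = segment.frames[n]
    if not (
        np.array_equal(replayed.positions, stored.positions)
        and np.array_equal(replayed.velocities, stored.velocities)
    ):
        raise ReplayError(
            f"segment {segment.segment_index}: replay of frame {n} diverged "
            "from the stored trajectory"
        )
    return replayed


def build_disulfide_restraints(
    topology: Topology,
    pair: tuple[int, int],
    config: ControllerConfig,
    frame: Frame | None = None,
) -> RestraintSet:
    """Artificial restraints emulating a disulfide between sulfur ``pair``.

    One S–S distance restraint, a C-S-S and an S-S-C angle restraint (when
    the sulfurs have backbone anchors), and one C-S-S-C dihedral restraint
    whose target sign is taken from the geometry at ramp start (disulfides
    occupy the +90/-90 degree minima symmetrically).
    """
    s1, s2 = ordered_pair(*pair)
    rs = RestraintSet(
        distances=[
            DistanceRestraint(
                pair=(s1, s2),
                target=config.ss_target,
                force_constant=config.ss_force_constant,
            )
        ]
    )
    a1 = topology.site_anchor.get(s1)
    a2 = topology.site_anchor.get(s2)
    for triple in ((a1, s1, s2), (a2, s2, s1)):
        if triple[0] is not None:
            rs.angles.append(
                AngleRestraint(
                    triple=triple,
                    target=config.angle_target,
                    force_constant=config.angle_force_constant,
                )
            )
    if a1 is not None and a2 is not None:
        target = config.dihedral_target_abs
        if frame is not None:
            phi = _dihedral(
                frame.positions[a1],
                frame.positions[s1],
                frame.positions[s2],
                frame.positions[a2],
            )
            if phi < 0:
                target = -target
        rs.dihedrals.append(
            DihedralRestraint(
                quad=(a1, s1, s2, a2),
                target=target,
                force_constant=config.dihedral_force_constant,
            )
        )
    return rs


def ramp_topology(topology: Topology, pair: tuple[int, int]) -> Topology:
    """Topology used while ramping restraints for ``pair``: a zero-strength
    scaffold bond marks the nascent disulfide in the bond graph so that its
    1-2/1-3 nonbonded exclusions apply during the ramp exactly as they will
    after the permanent bond is installed.  The scaffold contributes no
    energy; the hand-off to the real bond is therefore exactly
    energy-neutral."""
    s1, s2 = ordered_pair(*pair)
    topo = topology.copy()
    topo.bonds.append(BondTerm(s1, s2, 0.0, 2.038))
    return topo


def run_ramp(
    state: Frame,
    topology: Topology,
    pair: tuple[int, int],
    restraints: RestraintSet,
    schedule: RampSchedule,
    config: ControllerConfig,
    record_every_ps: float | None = None,
) -> tuple[Frame, list[Frame], list[tuple[float, float]]]:
    """Ramp the artificial restraints from 1/n to 1 over the schedule.

    alpha is held constant within each window.  Returns the final frame,
    frames recorded at ``record_every_ps`` (defaults to the window length),
    and the applied (time, alpha) series.  A distance diverging from target
    over three consecutive windows raises :class:`RampFailureError`.
    """
    prop = Propagator(
        ramp_topology(topology, pair),
        dt=config.dt,
        gamma=config.gamma,
        temperature=config.temperature,
        sphere_radius=config.sphere_radius,
        lj_mode=config.lj_mode,
        mask_onset=config.mask_onset,
    )
    prop.set_restraints(restraints)
    steps_per_window = max(1, round(schedule.step_duration / config.dt))
    if record_every_ps is None:
        record_every = steps_per_window
    else:
        record_every = max(1, round(record_every_ps / config.dt))
        if steps_per_window % record_every:
            raise ConfigError("recording interval must divide the ramp window")
    frame = state
    recorded: list[Frame] = []
    alpha_series: list[tuple[float, float]] = []
    s1, s2 = pair
    target = restraints.distances[0].target if restraints.distances else None
    deviations: list[float] = []
    for k in range(1, schedule.n_steps + 1):
        alpha = schedule.scale_at(k)
        alpha_series.append((frame.time, alpha))
        chunk = prop.run(
            frame, steps_per_window, alpha=alpha, record_every=record_every
        )
        recorded.extend(chunk)
        frame = chunk[-1]
        if target is not None:
            dev = abs(frame.distance(s1, s2) - target)
            deviations.append(dev)
            if (
                len(deviations) >= 3
                and deviations[-1] > deviations[-2] > deviations[-3]
                and deviations[-1] > 2.0
            ):
                raise RampFailureError(
                    f"S–S distance diverging from {target} Å over three "
                    f"windows (last deviations {deviations[-3:]}), pair {pair}"
                )
    return frame, recorded, alpha_series


def form_disulfide(
    topology: Topology,
    pair: tuple[int, int],
    config: ControllerConfig,
    restraints: RestraintSet | None = None,
) -> Topology:
    """Replace the fully-ramped restraints with a permanent disulfide.

    The new bonded terms carry exactly the restraint targets and full force
    constants, so the energy is unchanged at the moment of hand-off.  Both
    sulfurs leave the reactive registry, their residues become XCYS, and
    every mask entry involving them is dropped.
    """
    s1, s2 = ordered_pair(*pair)
    topo = topology.copy()
    if s1 not in topo.reactive_sites or s2 not in topo.reactive_sites:
        raise TopologyError(f"pair {pair} not fully reactive; cannot bond")
    if restraints is None:
        restraints = build_disulfide_restraints(topo, (s1, s2), config)
    for r in restraints.distances:
        topo.bonds.append(BondTerm(*r.pair, r.force_constant, r.target))
    for r in restraints.angles:
        topo.angles.append(AngleTerm(*r.triple, r.force_constant, r.target))
    for r in restraints.dihedrals:
        topo.dihedrals.append(DihedralTerm(*r.quad, r.force_constant, r.target))
    topo.reactive_sites = [s for s in topo.reactive_sites if s not in (s1, s2)]
    topo.disulfides.add((s1, s2))
    for s in (s1, s2):
        res = topo.particle_residue[s]
        if topo.residue_labels[res] == RCYS:
            topo.residue_labels[res] = XCYS
    topo.refresh_mask()
    topo.validate()
    return topo


def _exposure(topology: Topology, frame: Frame, pair: tuple[int, int], fn: str) -> float:
    if fn == "uniform":
        return 1.0
    # buriedness proxy: fewer beads near the S–S midpoint -> more exposed
    mid = 0.5 * (frame.positions[pair[0]] + frame.positions[pair[1]])
    skip = {pair[0], pair[1]}
    skip.update(
        a for s, a in topology.site_anchor.items() if s in (pair[0], pair[1])
    )
    close = 0
    for p in range(topology.n_particles):
        if p in skip:
            continue
        if float(np.linalg.norm(frame.positions[p] - mid)) < 6.5:
            close += 1
    return 1.0 / (1.0 + close)


def maybe_reduce(
    topology: Topology,
    frame: Frame,
    config: ReductionConfig,
    rng: np.random.Generator,
    controller: ControllerConfig | None = None,
) -> tuple[Topology, list[BondEvent]]:
    """Reverse step: each formed disulfide is reduced with probability
    base_prob x exposure(pair) per decision.  Returns the (possibly new)
    topology and any 'reduced' events."""
    if not config.enabled or not topology.disulfides:
        return topology, []
    controller = controller or ControllerConfig()
    events: list[BondEvent] = []
    topo = topology
    for pair in sorted(topology.disulfides):
        p = config.base_prob * _exposure(topology, frame, pair, config.exposure_fn)
        if rng.random() < p:
            topo = _break_disulfide(topo, pair)
            events.append(
                BondEvent(
                    pair=pair,
                    residues=(
                        topo.particle_residue[pair[0]] + 1,
                        topo.particle_residue[pair[1]] + 1,
                    ),
                    trigger_time=frame.time,
                    trigger_frame=-1,
                    trigger_distance=frame.distance(*pair),
                    gate_draws=0,
                    kind="reduced",
                )
            )
    return topo, events


def _break_disulfide(topology: Topology, pair: tuple[int, int]) -> Topology:
    """Exact inverse of :func:`form_disulfide` for one pair."""
    s1, s2 = ordered_pair(*pair)
    topo = topology.copy()
    if (s1, s2) not in topo.disulfides:
        raise TopologyError(f"{pair} is not a formed disulfide")
    topo.disulfides.discard((s1, s2))
    both = {s1, s2}
    topo.bonds = [b for b in topo.bonds if {b.i, b.j} != both]
    topo.angles = [a for a in topo.angles if not both <= {a.i, a.j, a.k}]
    topo.dihedrals = [d for d in topo.dihedrals if not both <= {d.i, d.j, d.k, d.l}]
    topo.reactive_sites = sorted(topo.reactive_sites + [s1, s2])
    for s in (s1, s2):
        res = topo.particle_residue[s]
        if topo.residue_labels[res] == XCYS:
            topo.residue_labels[res] = RCYS
    topo.refresh_mask()
    topo.validate()
    return topo


# ---------------------------------------------------------------------------
# The full three-stage run
# ---------------------------------------------------------------------------

@dataclass
class FoldingResult:
    """Outcome of a three-stage oxidative-folding run."""

    frames: list[Frame]
    events: list[BondEvent]
    topology: Topology
    status: str                      # "complete" | "unbonded-remaining"
    segments: list[SegmentRecord] = field(default_factory=list)
    alpha_history: list[tuple[float, float]] = field(default_factory=list)
    stage_boundaries: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def formed(self) -> list[BondEvent]:
        return [e for e in self.events if e.kind == "formed"]


def _conventional_topology(topology: Topology) -> Topology:
    """Topology with the reactive mask inactive (standard potential)."""
    topo = topology.copy()
    topo.lj_mask = set()
    return topo


@dataclass
class Checkpoint:
    """Resumable controller state, recorded at a segment boundary."""

    topology: Topology
    frame: Frame
    folding_elapsed: float
    seg_index: int
    rejected: int
    gate_state: dict
    red_state: dict
    events: list[BondEvent]
    t_fold_start: float

    def to_dict(self) -> dict:
        return {
            "topology": self.topology.to_dict(),
            "frame": self.frame.to_dict(),
            "folding_elapsed": self.folding_elapsed,
            "seg_index": self.seg_index,
            "rejected": self.rejected,
            "gate_state": self.gate_state,
            "red_state": self.red_state,
            "events": [e.to_dict() for e in self.events],
            "t_fold_start": self.t_fold_start,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Checkpoint":
        return cls(
            topology=Topology.from_dict(d["topology"]),
            frame=Frame.from_dict(d["frame"]),
            folding_elapsed=d["folding_elapsed"],
            seg_index=d["seg_index"],
            rejected=d["rejected"],
            gate_state=d["gate_state"],
            red_state=d["red_state"],
            events=[BondEvent.from_dict(e) for e in d["events"]],
            t_fold_start=d["t_fold_start"],
        )


def run_oxidative_folding(
    topology: Topology,
    frame: Frame,
    config: ControllerConfig,
    on_segment=None,
    resume: Checkpoint | None = None,
) -> FoldingResult:
    """Equilibration under the standard potential, then the segmented
    capture/gate/ramp/bond loop until no reactive pair remains (or the
    folding-time cap is hit), then a conventional extension.

    ``on_segment(checkpoint, segment)`` is invoked after every stage-2
    segment with the pre-segment controller state (enough to resume) and
    the recorded segment.  Passing a previously captured ``resume``
    checkpoint skips equilibration and continues stage 2 from it.
    """
    topology.validate()
    ss = np.random.SeedSequence(config.seed)
    dyn_seed, gate_seed, red_seed = ss.spawn(3)
    gate_rng = np.random.default_rng(gate_seed)
    red_rng = np.random.default_rng(red_seed)

    if frame.rng_state is None:
        frame = frame.copy()
        frame.rng_state = np.random.default_rng(dyn_seed).bit_generator.state

    steps_per_frame = max(1, round(config.frame_interval / config.dt))
    eq_len, fold_cap, ext_len = config.stage_lengths

    def make_prop(topo: Topology) -> Propagator:
        return Propagator(
            topo,
            dt=config.dt,
            gamma=config.gamma,
            temperature=config.temperature,
            sphere_radius=config.sphere_radius,
            lj_mode=config.lj_mode,
            mask_onset=config.mask_onset,
        )

    traj: list[Frame] = [frame.copy()]
    events: list[BondEvent] = []
    segments: list[SegmentRecord] = []
    alpha_history: list[tuple[float, float]] = []

    if resume is not None:
        topology = resume.topology
        frame = resume.frame
        gate_rng.bit_generator.state = resume.gate_state
        red_rng.bit_generator.state = resume.red_state
        events = list(resume.events)
        rejected_since_event = resume.rejected
        folding_elapsed = resume.folding_elapsed
        seg_index = resume.seg_index
        t_fold_start = resume.t_fold_start
        traj = [frame.copy()]
    else:
        # ---- stage 1: equilibration, standard potential -----------------
        if eq_len > 0:
            prop = make_prop(_conventional_topology(topology))
            n_frames = max(1, round(eq_len / config.frame_interval))
            chunk = prop.run(
                frame, n_frames * steps_per_frame, record_every=steps_per_frame
            )
            traj.extend(chunk)
            frame = chunk[-1]
        t_fold_start = frame.time
        rejected_since_event = 0
        folding_elapsed = 0.0
        seg_index = 0

    # ---- stage 2: oxidative folding -------------------------------------
    while len(topology.reactive_sites) >= 2 and folding_elapsed < fold_cap - 1e-9:
        prop = make_prop(topology)
        seg_len = min(config.segment_length, fold_cap - folding_elapsed)
        n_frames = max(1, round(seg_len / config.frame_interval))
        restart = frame.copy()
        pre_state = (
            Checkpoint(
                topology=topology.copy(),
                frame=restart.copy(),
                folding_elapsed=folding_elapsed,
                seg_index=seg_index,
                rejected=rejected_since_event,
                gate_state=gate_rng.bit_generator.state,
                red_state=red_rng.bit_generator.state,
                events=list(events),
                t_fold_start=t_fold_start,
            )
            if on_segment is not None
            else None
        )
        seg_frames = prop.run(
            frame, n_frames * steps_per_frame, record_every=steps_per_frame
        )
        segment = SegmentRecord(seg_index, restart, seg_frames)
        segments.append(segment)
        seg_index += 1
        if on_segment is not None:
            on_segment(pre_state, segment)

        if config.accept_prob >= 1.0:
            hit = detect_capture(segment, topology, config.capture_radius)
            hit = None if hit is None else (hit[0], hit[1], 0)
        else:
            hit = _scan_with_gate(
                segment, topology, config.capture_radius, config.accept_prob, gate_rng
            )
            if hit is not None and hit[0] < 0:
                rejected_since_event += hit[2]
                hit = None

        if hit is None:
            traj.extend(seg_frames)
            frame = seg_frames[-1]
            folding_elapsed += n_frames * config.frame_interval
            if config.reduction.enabled:
                new_topo, red_events = maybe_reduce(
                    topology, frame, config.reduction, red_rng, config
                )
                if red_events:
                    topology = new_topo
                    events.extend(red_events)
            continue

        n, pair, rejected = hit
        rejected_since_event += rejected
        crossing = rewind_to_crossing(segment, n, prop, steps_per_frame)
        traj.extend(seg_frames[: n + 1])
        folding_elapsed += (n + 1) * config.frame_interval

        restraints = build_disulfide_restraints(topology, pair, config, crossing)
        final, ramp_frames, alphas = run_ramp(
            crossing, topology, pair, restraints, config.ramp, config
        )
        traj.extend(ramp_frames)
        alpha_history.extend(alphas)
        events.append(
            BondEvent(
                pair=pair,
                residues=(
                    topology.particle_residue[pair[0]] + 1,
                    topology.particle_residue[pair[1]] + 1,
                ),
                trigger_time=crossing.time - t_fold_start,
                trigger_frame=len(traj) - len(ramp_frames) - 1,
                trigger_distance=crossing.distance(*pair),
                gate_draws=rejected_since_event,
                kind="formed",
            )
        )
        rejected_since_event = 0
        topology = form_disulfide(topology, pair, config, restraints)
        frame = final

    status = "complete" if len(topology.reactive_sites) < 2 else "unbonded-remaining"
    t_ext_start = frame.time

    # ---- stage 3: extension, conventional -------------------------------
    if ext_len > 0:
        prop = make_prop(_conventional_topology(topology))
        n_frames = max(1, round(ext_len / config.frame_interval))
        chunk = prop.run(frame, n_frames * steps_per_frame, record_every=steps_per_frame)
        traj.extend(chunk)
        frame = chunk[-1]

    return FoldingResult(
        frames=traj,
        events=events,
        topology=topology,
        status=status,
        segments=segments,
        alpha_history=alpha_history,
        stage_boundaries=(t_fold_start, t_ext_start, frame.time),
    )
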