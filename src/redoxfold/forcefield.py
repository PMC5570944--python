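"""Energies, forces and Langevin propagation for the coarse-grained chain.

The engine honours the reactive-pair LJ mask and any active (ramp-scaled)
restraints.  The integrator is a BAOAB Langevin splitting: with collision
frequency gamma = 0 it reduces to velocity Verlet (NVE), and at gamma > 0
it samples the canonical ensemble at the requested temperature.  Gaussian
noise is drawn from a numpy Generator whose state is recorded on every
stored frame, so any stretch of trajectory can be replayed bitwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import GeometryError, TopologyError, IntegrationBlowupError
from .model_core import (
    Frame,
    PairPotentialParams,
    RestraintSet,
    Topology,
    ordered_pair,
)
from .units import FORCE_TO_ACCEL, KB

__all__ = [
    "EnergyBreakdown",
    "lj_pair_energy",
    "restraint_energy",
    "total_energy",
    "total_forces",
    "langevin_step",
    "Propagator",
]

#: Default onset below which a masked reactive S–S pair feels no LJ.  Beyond
#: it the pair interacts normally, so the trajectory is exactly the standard
#: one whenever all reactive pairs stay outside this radius.
DEFAULT_MASK_ONSET = 3.5


@dataclass(frozen=True)
class EnergyBreakdown:
    bond: float
    angle: float
    dihedral: float
    lj: float
    restraint: float

    @property
    def total(self) -> float:
        return self.bond + self.angle + self.dihedral + self.lj + self.restraint


def lj_pair_energy(
    r: float,
    params: PairPotentialParams,
    masked: bool = False,
    mask_onset: float = DEFAULT_MASK_ONSET,
) -> float:
    """Pairwise LJ energy ε((r0/r)¹² − 2(r0/r)⁶), truncated at the cutoff.

    A masked pair (two reactive sulfurs) feels nothing below ``mask_onset``:
    the repulsive wall that would stop the sulfurs short of the capture
    radius is removed, while beyond the onset the term is untouched.
    """
    if r <= 0:
        raise GeometryError(f"non-positive pair distance {r}")
    if r >= params.cutoff:
        return 0.0
    if masked and r < mask_onset:
        return 0.0
    s6 = (params.r0 / r) ** 6
    return params.epsilon * (s6 * s6 - 2.0 * s6)


def restraint_energy(frame: Frame, restraints: RestraintSet, alpha: float) -> float:
    """Energy of the artificial disulfide restraints at ramp scale ``alpha``.

    Angle/dihedral deviations are taken in radians; the dihedral deviation
    is wrapped to the shortest arc.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    n = frame.positions.shape[0]
    for idx in restraints.particle_indices():
        if not 0 <= idx < n:
            raise TopologyError(f"restraint references particle {idx} out of range")
    pos = frame.positions
    e = 0.0
    for r in restraints.distances:
        d = float(np.linalg.norm(pos[r.pair[0]] - pos[r.pair[1]]))
        e += alpha * r.force_constant * (d - r.target) ** 2
    for r in restraints.angles:
        i, j, k = r.triple
        theta = _angle(pos[i], pos[j], pos[k])
        e += alpha * r.force_constant * (theta - math.radians(r.target)) ** 2
    for r in restraints.dihedrals:
        i, j, k, l = r.quad
        phi = _dihedral(pos[i], pos[j], pos[k], pos[l])
        dev = _wrap(phi - math.radians(r.target))
        e += alpha * r.force_constant * dev**2
    return e


def _angle(a, b, c) -> float:
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _dihedral(a, b, c, d) -> float:
    b1, b2, b3 = b - a, c - b, d - c
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m = np.cross(n1, n2)
    y = np.dot(m, b2) / np.linalg.norm(b2)
    x = np.dot(n1, n2)
    return float(np.arctan2(y, x))


def _wrap(x: float) -> float:
    x = x - 2.0 * math.pi * round(x / (2.0 * math.pi))
    if x <= -math.pi:
        x += 2.0 * math.pi
    return x


# ---------------------------------------------------------------------------
# Array tables for the kernels
# ---------------------------------------------------------------------------

_EMPTY_I = np.empty(0, dtype=np.int64)
_EMPTY_F = np.empty(0, dtype=np.float64)


class _FFTables:
    """Flat-array view of a topology (+ optional restraints) for the kernels."""

    def __init__(
        self,
        topology: Topology,
        lj_mode: str = "masked",
        mask_onset: float = DEFAULT_MASK_ONSET,
        shrunk_r0: float = 2.0,
    ):
        topology.validate()
        self.n = topology.n_particles
        self.masses = np.asarray(topology.masses, dtype=float)

        b = topology.bonds
        self.bond_i = np.array([t.i for t in b], dtype=np.int64)
        self.bond_j = np.array([t.j for t in b], dtype=np.int64)
        self.bond_k = np.array([t.force_constant for t in b], dtype=float)
        self.bond_r0 = np.array([t.r0 for t in b], dtype=float)

        a = topology.angles
        self.ang_i = np.array([t.i for t in a], dtype=np.int64)
        self.ang_j = np.array([t.j for t in a], dtype=np.int64)
        self.ang_k = np.array([t.k for t in a], dtype=np.int64)
        self.ang_kf = np.array([t.force_constant for t in a], dtype=float)
        self.ang_t0 = np.array([math.radians(t.theta0) for t in a], dtype=float)

        d = topology.dihedrals
        self.dih_i = np.array([t.i for t in d], dtype=np.int64)
        self.dih_j = np.array([t.j for t in d], dtype=np.int64)
        self.dih_k = np.array([t.k for t in d], dtype=np.int64)
        self.dih_l = np.array([t.l for t in d], dtype=np.int64)
        self.dih_kf = np.array([t.force_constant for t in d], dtype=float)
        self.dih_t0 = np.array([math.radians(t.phi0) for t in d], dtype=float)

        excl = topology.exclusions()
        params = topology.lj_params
        pi, pj, eps, r0, masked = [], [], [], [], []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if (i, j) in excl:
                    continue
                pi.append(i)
                pj.append(j)
                eps.append(params.epsilon)
                in_mask = ordered_pair(i, j) in topology.lj_mask
                if in_mask and lj_mode == "shrunk_r0":
                    r0.append(shrunk_r0)
                    masked.append(0)
                else:
                    r0.append(params.r0)
                    masked.append(1 if in_mask else 0)
        self.pair_i = np.array(pi, dtype=np.int64)
        self.pair_j = np.array(pj, dtype=np.int64)
        self.pair_eps = np.array(eps, dtype=float)
        self.pair_r0 = np.array(r0, dtype=float)
        self.pair_masked = np.array(masked, dtype=np.int64)
        self.cutoff = params.cutoff
        self.mask_onset = mask_onset

        self.set_restraints(None)

    def set_restraints(self, restraints: RestraintSet | None):
        if restraints is None:
            restraints = RestraintSet()
        for idx in restraints.particle_indices():
            if not 0 <= idx < self.n:
                raise TopologyError(f"restraint references particle {idx} out of range")
        rd = restraints.distances
        self.rd_i = np.array([r.pair[0] for r in rd], dtype=np.int64)
        self.rd_j = np.array([r.pair[1] for r in rd], dtype=np.int64)
        self.rd_k = np.array([r.force_constant for r in rd], dtype=float)
        self.rd_t = np.array([r.target for r in rd], dtype=float)
        ra = restraints.angles
        self.ra_i = np.array([r.triple[0] for r in ra], dtype=np.int64)
        self.ra_j = np.array([r.triple[1] for r in ra], dtype=np.int64)
        self.ra_k = np.array([r.triple[2] for r in ra], dtype=np.int64)
        self.ra_kf = np.array([r.force_constant for r in ra], dtype=float)
        self.ra_t0 = np.array([math.radians(r.target) for r in ra], dtype=float)
        rq = restraints.dihedrals
        self.rq_i = np.array([r.quad[0] for r in rq], dtype=np.int64)
        self.rq_j = np.array([r.quad[1] for r in rq], dtype=np.int64)
        self.rq_k = np.array([r.quad[2] for r in rq], dtype=np.int64)
        self.rq_l = np.array([r.quad[3] for r in rq], dtype=np.int64)
        self.rq_kf = np.array([r.force_constant for r in rq], dtype=float)
        self.rq_t0 = np.array([math.radians(r.target) for r in rq], dtype=float)

    def ff_args(self, alpha: float):
        return (
            self.bond_i, self.bond_j, self.bond_k, self.bond_r0,
            self.ang_i, self.ang_j, self.ang_k, self.ang_kf, self.ang_t0,
            self.dih_i, self.dih_j, self.dih_k, self.dih_l, self.dih_kf, self.dih_t0,
            self.pair_i, self.pair_j, self.pair_eps, self.pair_r0, self.pair_masked,
            self.cutoff, self.mask_onset,
            self.rd_i, self.rd_j, self.rd_k, self.rd_t,
            self.ra_i, self.ra_j, self.ra_k, self.ra_kf, self.ra_t0,
            self.rq_i, self.rq_j, self.rq_k, self.rq_l, self.rq_kf, self.rq_t0,
            float(alpha),
        )


def _check_overlaps(pos: np.ndarray):
    n = pos.shape[0]
    if n < 2:
        return
    d = pos[:, None, :] - pos[None, :, :]
    r = np.sqrt((d * d).sum(axis=-1))
    r[np.diag_indices(n)] = np.inf
    if r.min() < 1e-6:
        i, j = np.unravel_index(np.argmin(r), r.shape)
        raise GeometryError(f"particles {i} and {j} overlap (r = {r.min():.2e} Å)")


def total_energy(
    frame: Frame,
    topology: Topology,
    restraints: RestraintSet | None = None,
    alpha: float = 0.0,
    lj_mode: str = "masked",
    mask_onset: float = DEFAULT_MASK_ONSET,
) -> EnergyBreakdown:
    """Full energy breakdown of a frame."""
    tab = _FFTables(topology, lj_mode=lj_mode, mask_onset=mask_onset)
    tab.set_restraints(restraints)
    forces = np.zeros((tab.n, 3))
    eb, ea, ed, el, er = _kernels.compute_forces(
        frame.positions, forces, *tab.ff_args(alpha)
    )
    return EnergyBreakdown(bond=eb, angle=ea, dihedral=ed, lj=el, restraint=er)


def total_forces(
    frame: Frame,
    topology: Topology,
    restraints: RestraintSet | None = None,
    alpha: float = 0.0,
    lj_mode: str = "masked",
    mask_onset: float = DEFAULT_MASK_ONSET,
) -> np.ndarray:
    """Per-particle forces, kcal/mol/Å; the exact negative energy gradient."""
    _check_overlaps(frame.positions)
    tab = _FFTables(topology, lj_mode=lj_mode, mask_onset=mask_onset)
    tab.set_restraints(restraints)
    forces = np.zeros((tab.n, 3))
    _kernels.compute_forces(frame.positions, forces, *tab.ff_args(alpha))
    return forces


# ---------------------------------------------------------------------------
# Propagation
# ---------------------------------------------------------------------------

class Propagator:
    """Chunked BAOAB Langevin propagator over a fixed topology.

    One instance is valid as long as the topology (bonded terms, mask) does
    not change; the controller rebuilds it after every bonding event.
    """

    def __init__(
        self,
        topology: Topology,
        dt: float = 0.002,
        gamma: float = 2.0,
        temperature: float = 293.0,
        sphere_radius: float = 60.0,
        lj_mode: str = "masked",
        mask_onset: float = DEFAULT_MASK_ONSET,
    ):
        if dt <= 0 or gamma < 0 or temperature < 0:
            raise ValueError("require dt > 0, gamma >= 0, T >= 0")
        self.tables = _FFTables(topology, lj_mode=lj_mode, mask_onset=mask_onset)
        self.dt = dt
        self.gamma = gamma
        self.temperature = temperature
        self.sphere_radius = sphere_radius
        m = self.tables.masses
        self._accel = FORCE_TO_ACCEL / m
        c1 = math.exp(-gamma * dt)
        self._c1 = c1
        self._sigma_v = np.sqrt(
            max(0.0, 1.0 - c1 * c1) * KB * temperature * FORCE_TO_ACCEL / m
        )

    def set_restraints(self, restraints: RestraintSet | None):
        self.tables.set_restraints(restraints)

    @staticmethod
    def _generator(frame: Frame, seed: int | None = None) -> np.random.Generator:
        rng = np.random.Generator(np.random.PCG64())
        if frame.rng_state is not None:
            rng.bit_generator.state = frame.rng_state
        elif seed is not None:
            return np.random.Generator(np.random.PCG64(seed))
        return rng

    def run(
        self,
        frame: Frame,
        n_steps: int,
        alpha: float = 0.0,
        record_every: int | None = None,
        seed: int | None = None,
    ) -> list[Frame]:
        """Advance ``n_steps`` integrator steps from ``frame``.

        Returns recorded frames (each carrying the RNG state at its moment)
        every ``record_every`` steps, or just the final frame.  The input
        frame is not modified.
        """
        if record_every is None:
            record_every = n_steps
        if n_steps % record_every:
            raise ValueError("record_every must divide n_steps")
        rng = self._generator(frame, seed)
        pos = frame.positions.copy()
        vel = frame.velocities.copy()
        t = frame.time
        out: list[Frame] = []
        args = self.tables.ff_args(alpha)
        for chunk in range(n_steps // record_every):
            noise = rng.standard_normal((record_every, self.tables.n, 3))
            bad = _kernels.run_chunk(
                pos, vel, self._accel, self._sigma_v, self._c1,
                self.dt, record_every, noise, self.sphere_radius, *args,
            )
            if bad:
                raise IntegrationBlowupError(
                    f"non-finite coordinates at step {chunk * record_every + bad} "
                    f"(t = {t + (chunk * record_every + bad) * self.dt:.4f} ps)"
                )
            t = frame.time + (chunk + 1) * record_every * self.dt
            out.append(
                Frame(
                    time=t,
                    positions=pos.copy(),
                    velocities=vel.copy(),
                    rng_state=rng.bit_generator.state,
                )
            )
        return out

    def energy(self, frame: Frame, alpha: float = 0.0) -> EnergyBreakdown:
        forces = np.zeros((self.tables.n, 3))
        eb, ea, ed, el, er = _kernels.compute_forces(
            frame.positions, forces, *self.tables.ff_args(alpha)
        )
        return EnergyBreakdown(bond=eb, angle=ea, dihedral=ed, lj=el, restraint=er)


def langevin_step(
    frame: Frame,
    topology: Topology,
    restraints: RestraintSet | None = None,
    alpha: float = 0.0,
    dt: float = 0.002,
    gamma: float = 2.0,
    temperature: float = 293.0,
    seed: int | None = None,
    lj_mode: str = "masked",
    sphere_radius: float = 60.0,
) -> Frame:
    """Advance exactly one BAOAB step; gamma = 0 reduces to velocity Verlet."""
    prop = Propagator(
        topology,
        dt=dt,
        gamma=gamma,
        temperature=temperature,
        sphere_radius=sphere_radius,
        lj_mode=lj_mode,
    )
    prop.set_restraints(restraints)
    return prop.run(frame, 1, alpha=alpha, seed=seed)[0]
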