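"""Domain types shared across redoxfold: topology, frames, restraints, events.

The model is deliberately coarse: one backbone bead per residue plus one
sulfur bead bonded to each cysteine backbone bead (~1.8 Å).  Reactive
cysteines (residue code ``RCYS``, after the thiyl-like CYR type) carry a
sulfur bead whose pairwise Lennard-Jones repulsion against other reactive
sulfurs is switched off at short range so the pair can reach the capture
radius and bond.  Once bonded, both residues become ``XCYS`` (standard
disulfide-bonded cysteine) and all their interactions return to normal.

All quantities use the package unit system (Å, ps, kcal/mol, K, amu).
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigError, TopologyError, GeometryError

#: Residue type codes.
GENERIC = "GEN"
RCYS = "RCYS"  # reactive (deprotonated, neutral) cysteine
XCYS = "XCYS"  # disulfide-bonded cysteine


def ordered_pair(i: int, j: int) -> tuple[int, int]:
    """Canonical (sorted) form of an unordered particle pair."""
    if i == j:
        raise TopologyError(f"pair ({i},{j}) repeats a particle")
    return (i, j) if i < j else (j, i)


# ---------------------------------------------------------------------------
# Bonded terms (plain force-field terms, E = k * deviation**2, no 1/2)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BondTerm:
    i: int
    j: int
    force_constant: float  # kcal/mol/Å²
    r0: float              # Å


@dataclass(frozen=True)
class AngleTerm:
    i: int
    j: int
    k: int
    force_constant: float  # kcal/mol/rad²
    theta0: float          # degrees


@dataclass(frozen=True)
class DihedralTerm:
    i: int
    j: int
    k: int
    l: int
    force_constant: float  # kcal/mol/rad²
    phi0: float            # degrees, in (-180, 180]


# ---------------------------------------------------------------------------
# Restraints (artificial, scaled by the ramp factor alpha)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceRestraint:
    """Harmonic S–S distance restraint, energy alpha*k*(r - target)²."""

    pair: tuple[int, int]
    target: float = 2.038          # Å, equilibrium disulfide length
    force_constant: float = 166.0  # kcal/mol/Å²

    def __post_init__(self):
        if self.target <= 0:
            raise ConfigError("distance restraint target must be > 0")
        if self.force_constant <= 0:
            raise ConfigError("distance restraint force constant must be > 0")


@dataclass(frozen=True)
class AngleRestraint:
    """Harmonic angle restraint toward `target` degrees (C-S-S / S-S-C)."""

    triple: tuple[int, int, int]
    target: float = 103.7         # degrees
    force_constant: float = 68.0  # kcal/mol/rad²

    def __post_init__(self):
        if not 0.0 < self.target < 180.0:
            raise ConfigError("angle restraint target must lie in (0, 180)")


@dataclass(frozen=True)
class DihedralRestraint:
    """Harmonic dihedral restraint; deviation taken on the shortest arc."""

    quad: tuple[int, int, int, int]
    target: float = 90.0          # degrees, in (-180, 180]
    force_constant: float = 3.5   # kcal/mol/rad²

    def __post_init__(self):
        if not -180.0 < self.target <= 180.0:
            raise ConfigError("dihedral restraint target must lie in (-180, 180]")


@dataclass
class RestraintSet:
    distances: list[DistanceRestraint] = field(default_factory=list)
    angles: list[AngleRestraint] = field(default_factory=list)
    dihedrals: list[DihedralRestraint] = field(default_factory=list)

    def __len__(self):
        return len(self.distances) + len(self.angles) + len(self.dihedrals)

    def particle_indices(self):
        for r in self.distances:
            yield from r.pair
        for r in self.angles:
            yield from r.triple
        for r in self.dihedrals:
            yield from r.quad


@dataclass(frozen=True)
class RampSchedule:
    """Step-wise linear restraint ramp: alpha = k / n_steps, one 10-ps window
    per increment of k.  The first *applied* scale is 1/n_steps (k starts at
    1); scale_at(0) = 0 is the formal start of the schedule."""

    n_steps: int = 200
    step_duration: float = 10.0  # ps

    def __post_init__(self):
        if self.n_steps < 1 or self.step_duration <= 0:
            raise ConfigError("ramp schedule requires n_steps >= 1, step_duration > 0")

    def scale_at(self, k: int) -> float:
        if not 0 <= k <= self.n_steps:
            raise ConfigError(f"ramp index {k} outside [0, {self.n_steps}]")
        return k / self.n_steps

    @property
    def total_duration(self) -> float:
        return self.n_steps * self.step_duration


# ---------------------------------------------------------------------------
# Pair potential
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairPotentialParams:
    """Lennard-Jones in the r-min form ε((r0/r)¹² − 2(r0/r)⁶), truncated."""

    epsilon: float = 0.25  # kcal/mol
    r0: float = 4.0        # Å, minimum-energy distance
    cutoff: float = 10.5   # Å

    def __post_init__(self):
        if self.epsilon < 0:
            raise ConfigError("epsilon must be >= 0")
        if not 0 < self.r0 < self.cutoff:
            raise ConfigError("require 0 < r0 < cutoff")


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Coarse-grained chain topology with a reactive-site registry.

    Particles are 0-based.  ``reactive_sites`` lists the sulfur beads of
    RCYS residues; ``lj_mask`` holds the sulfur pairs whose short-range LJ
    is disabled; ``disulfides`` holds formed bonds.  Mutation on bonding is
    append-only in history: the ordered BondEvent sequence fully determines
    the final state.
    """

    residue_labels: list[str]
    particle_names: list[str]          # "CA" backbone bead, "SG" sulfur bead
    particle_residue: list[int]        # residue index per particle, 0-based
    masses: np.ndarray
    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    dihedrals: list[DihedralTerm] = field(default_factory=list)
    reactive_sites: list[int] = field(default_factory=list)
    disulfides: set[tuple[int, int]] = field(default_factory=set)
    lj_mask: set[tuple[int, int]] = field(default_factory=set)
    lj_params: PairPotentialParams = field(default_factory=PairPotentialParams)
    site_anchor: dict[int, int] = field(default_factory=dict)  # S bead -> backbone bead

    @property
    def n_particles(self) -> int:
        return len(self.particle_names)

    def validate(self) -> None:
        n = self.n_particles
        if not (len(self.particle_residue) == n and len(self.masses) == n):
            raise TopologyError("particle arrays disagree in length")
        sites = set(self.reactive_sites)
        if len(sites) != len(self.reactive_sites):
            raise TopologyError("duplicate reactive sites")
        for p in self.lj_mask:
            if not (p[0] in sites and p[1] in sites):
                raise TopologyError(f"lj_mask pair {p} outside reactive set")
        seen: set[int] = set()
        for p in self.disulfides:
            if p[0] in sites or p[1] in sites:
                raise TopologyError(f"disulfide {p} member still reactive")
            if p[0] in seen or p[1] in seen:
                raise TopologyError(f"particle in more than one disulfide: {p}")
            seen.update(p)
        for term in self.bonds:
            for idx in (term.i, term.j):
                if not 0 <= idx < n:
                    raise TopologyError(f"bond references particle {idx} out of range")

    def reactive_pairs(self) -> list[tuple[int, int]]:
        """All unordered pairs of currently reactive sulfur beads."""
        s = sorted(self.reactive_sites)
        return [(s[a], s[b]) for a in range(len(s)) for b in range(a + 1, len(s))]

    def refresh_mask(self) -> None:
        """Set lj_mask to exactly the reactive-pair set."""
        self.lj_mask = set(self.reactive_pairs())

    def exclusions(self) -> set[tuple[int, int]]:
        """1-2 and 1-3 nonbonded exclusions derived from the bond graph."""
        adj: dict[int, set[int]] = {i: set() for i in range(self.n_particles)}
        excl: set[tuple[int, int]] = set()
        for b in self.bonds:
            adj[b.i].add(b.j)
            adj[b.j].add(b.i)
            excl.add(ordered_pair(b.i, b.j))
        for center, nbrs in adj.items():
            lst = sorted(nbrs)
            for a in range(len(lst)):
                for b in range(a + 1, len(lst)):
                    excl.add(ordered_pair(lst[a], lst[b]))
        return excl

    def copy(self) -> "Topology":
        return _copy.deepcopy(self)

    # -- serialization (bit-exact round trip through plain dict / JSON) ----

    def to_dict(self) -> dict:
        return {
            "residue_labels": list(self.residue_labels),
            "particle_names": list(self.particle_names),
            "particle_residue": list(self.particle_residue),
            "masses": [float(m) for m in self.masses],
            "bonds": [asdict(b) for b in self.bonds],
            "angles": [asdict(a) for a in self.angles],
            "dihedrals": [asdict(d) for d in self.dihedrals],
            "reactive_sites": list(self.reactive_sites),
            "disulfides": sorted(list(p) for p in self.disulfides),
            "lj_mask": sorted(list(p) for p in self.lj_mask),
            "lj_params": asdict(self.lj_params),
            "site_anchor": {str(k): v for k, v in self.site_anchor.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Topology":
        return cls(
            residue_labels=list(d["residue_labels"]),
            particle_names=list(d["particle_names"]),
            particle_residue=list(d["particle_residue"]),
            masses=np.array(d["masses"], dtype=float),
            bonds=[BondTerm(**b) for b in d["bonds"]],
            angles=[AngleTerm(**a) for a in d["angles"]],
            dihedrals=[DihedralTerm(**t) for t in d["dihedrals"]],
            reactive_sites=list(d["reactive_sites"]),
            disulfides={tuple(p) for p in d["disulfides"]},
            lj_mask={tuple(p) for p in d["lj_mask"]},
            lj_params=PairPotentialParams(**d["lj_params"]),
            site_anchor={int(k): v for k, v in d["site_anchor"].items()},
        )


# ---------------------------------------------------------------------------
# Frame
# ---------------------------------------------------------------------------

@dataclass
class Frame:
    """A point of a trajectory: positions (Å), velocities (Å/ps), time (ps)
    and the RNG state token sufficient for bitwise replay of what follows."""

    time: float
    positions: np.ndarray
    velocities: np.ndarray
    rng_state: dict | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise GeometryError("non-finite positions in frame")
        if self.time < 0:
            raise GeometryError("frame time must be non-negative")

    def copy(self) -> "Frame":
        return Frame(
            time=self.time,
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            rng_state=_copy.deepcopy(self.rng_state),
        )

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.positions[i] - self.positions[j]))

    def to_dict(self) -> dict:
        return {
            "time": float(self.time),
            "positions": self.positions.tolist(),
            "velocities": self.velocities.tolist(),
            "rng_state": _copy.deepcopy(self.rng_state),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Frame":
        return cls(
            time=d["time"],
            positions=np.array(d["positions"], dtype=float),
            velocities=np.array(d["velocities"], dtype=float),
            rng_state=_copy.deepcopy(d.get("rng_state")),
        )


# ---------------------------------------------------------------------------
# Controller configuration
# ---------------------------------------------------------------------------

@dataclass
class ReductionConfig:
    """Optional reverse step: a formed disulfide is reduced back to two
    reactive thiols with a low per-decision probability, scaled by a solvent
    exposure proxy (glutathione accessibility in the physical picture)."""

    enabled: bool = False
    base_prob: float = 0.0
    exposure_fn: str = "uniform"  # or "buriedness"

    def __post_init__(self):
        if self.enabled and not 0.0 <= self.base_prob <= 1.0:
            raise ConfigError("reduction base_prob must lie in [0, 1]")
        if self.exposure_fn not in ("uniform", "buriedness"):
            raise ConfigError(f"unknown exposure_fn {self.exposure_fn!r}")


@dataclass
class ControllerConfig:
    """Parameters of the oxidative-folding controller.

    ``accept_prob`` is the per-contact-frame probability p0 that a close
    thiol encounter is productive (1.0: every encounter bonds; the
    reduced-reactivity protocol uses 0.001).  ``lj_mode`` selects between
    masking the reactive S–S LJ term at short range and shrinking its
    equilibrium distance r0 to 2 Å.
    """

    capture_radius: float = 2.5        # Å
    accept_prob: float = 1.0           # p0
    segment_length: float = 1000.0     # ps
    frame_interval: float = 1.0        # ps
    lj_mode: str = "masked"            # or "shrunk_r0"
    mask_onset: float = 3.5            # Å; masked S–S LJ is zero below this
    stage_lengths: tuple[float, float, float] = (1000.0, 10000.0, 1000.0)
    ramp: RampSchedule = field(default_factory=RampSchedule)
    # disulfide restraint / bonded-term parameters
    ss_target: float = 2.038           # Å
    ss_force_constant: float = 166.0   # kcal/mol/Å²
    angle_target: float = 103.7        # degrees (C-S-S and S-S-C)
    angle_force_constant: float = 68.0     # kcal/mol/rad²
    dihedral_target_abs: float = 90.0      # degrees, sign taken at ramp start
    dihedral_force_constant: float = 3.5   # kcal/mol/rad²
    # engine parameters
    dt: float = 0.002                  # ps
    gamma: float = 2.0                 # ps⁻¹
    temperature: float = 293.0         # K
    sphere_radius: float = 60.0        # Å, reflective container
    seed: int = 0
    reduction: ReductionConfig = field(default_factory=ReductionConfig)

    def __post_init__(self):
        if not 0.0 < self.accept_prob <= 1.0:
            raise ConfigError("accept_prob must lie in (0, 1]")
        if self.lj_mode not in ("masked", "shrunk_r0"):
            raise ConfigError(f"unknown lj_mode {self.lj_mode!r}")
        if self.capture_radius <= 0:
            raise ConfigError("capture_radius must be > 0")
        if self.frame_interval <= 0 or self.segment_length <= 0:
            raise ConfigError("frame_interval and segment_length must be > 0")
        ratio = self.segment_length / self.frame_interval
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigError("frame_interval must divide segment_length")
        if self.dt <= 0 or self.gamma < 0 or self.temperature < 0:
            raise ConfigError("require dt > 0, gamma >= 0, T >= 0")

    @classmethod
    def desk(cls, **overrides) -> "ControllerConfig":
        """Desk-scale preset for the coarse-grained fixture: short stages and
        a compressed ramp so a full folding run takes seconds, not hours."""
        base = dict(
            segment_length=100.0,
            stage_lengths=(50.0, 5000.0, 50.0),
            ramp=RampSchedule(n_steps=50, step_duration=2.0),
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def published_scale(cls, **overrides) -> "ControllerConfig":
        """Named preset with the published stage lengths (100 ns equilibration,
        1 µs folding cap, 450 ns extension) and the full 200 x 10 ps ramp."""
        base = dict(
            segment_length=1000.0,
            stage_lengths=(100_000.0, 1_000_000.0, 450_000.0),
            ramp=RampSchedule(n_steps=200, step_duration=10.0),
        )
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# Bond events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BondEvent:
    """One topology mutation: a disulfide formed (or reduced)."""

    pair: tuple[int, int]          # sulfur particle indices
    residues: tuple[int, int]      # 1-based cysteine residue numbers
    trigger_time: float            # ps
    trigger_frame: int
    trigger_distance: float        # Å
    gate_draws: int                # rejected gate decisions before acceptance
    kind: str = "formed"           # or "reduced"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pair"] = list(self.pair)
        d["residues"] = list(self.residues)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BondEvent":
        return cls(
            pair=tuple(d["pair"]),
            residues=tuple(d["residues"]),
            trigger_time=d["trigger_time"],
            trigger_frame=d["trigger_frame"],
            trigger_distance=d["trigger_distance"],
            gate_draws=d["gate_draws"],
            kind=d.get("kind", "formed"),
        )
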