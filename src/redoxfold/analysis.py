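"""Trajectory and ensemble statistics for oxidative-folding runs.

Covers isomer bookkeeping (which complete cysteine pairing a run produced,
or committed to with its first bond), kinetic footprints (first/second
bond times per trajectory), radius of gyration, ensemble RMSD with optimal
rigid-body superposition, NOE-restraint violation scoring with r⁻⁶
averaging over equivalent protons, and small geometry utilities.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import ConfigError, GeometryError, TopologyError
from .model_core import BondEvent, Frame, Topology, ordered_pair

__all__ = [
    "IsomerLabel",
    "NOERestraint",
    "radius_of_gyration",
    "enumerate_pairings",
    "classify_isomer",
    "kinetic_footprint",
    "superpose",
    "pairwise_rmsd",
    "ensemble_rmsd",
    "lowest_pairwise_rmsd",
    "StructureView",
    "noe_violation",
    "ss_distance_series",
    "truncated_octahedron_diameter",
]


# ---------------------------------------------------------------------------
# Radius of gyration
# ---------------------------------------------------------------------------

def radius_of_gyration(frame: Frame, selection=None, masses=None) -> float:
    """Mass-weighted RMS distance from the centre of mass, Å.

    ``selection`` is an index array (default: all particles); ``masses``
    defaults to unit weights.
    """
    pos = frame.positions
    if selection is not None:
        selection = np.asarray(selection, dtype=int)
        if selection.size == 0:
            raise ConfigError("empty selection")
        pos = pos[selection]
    if pos.shape[0] == 0:
        raise ConfigError("empty selection")
    if masses is None:
        w = np.ones(pos.shape[0])
    else:
        w = np.asarray(masses, dtype=float)
        if selection is not None and w.shape[0] != pos.shape[0]:
            w = w[selection]
    com = np.average(pos, axis=0, weights=w)
    sq = ((pos - com) ** 2).sum(axis=1)
    return float(np.sqrt(np.average(sq, weights=w)))


# ---------------------------------------------------------------------------
# Isomer bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsomerLabel:
    """A (possibly partial) disulfide pairing and its isomer assignment.

    ``label`` is one of isomer1/isomer2/isomer3/partial/none; a partial
    pairing also records the isomer it commits to (unique with four
    cysteines).
    """

    label: str
    pairing: frozenset = frozenset()
    committed: str | None = None


def enumerate_pairings(cys_positions) -> list[set[tuple[int, int]]]:
    """All perfect matchings of the positions; (n-1)!! of them."""
    positions = sorted(cys_positions)
    if len(positions) % 2:
        raise ConfigError("odd number of cysteine positions cannot be fully paired")
    if not positions:
        return [set()]
    out = []
    first, rest = positions[0], positions[1:]
    for i, partner in enumerate(rest):
        remainder = rest[:i] + rest[i + 1 :]
        for sub in enumerate_pairings(remainder):
            out.append({(first, partner)} | sub)
    return out


def _isomer_index(pairing: set[tuple[int, int]], positions) -> int:
    """1-based isomer number by the partner of the lowest cysteine:
    paired with the 2nd lowest -> isomer 1, 3rd -> 2, 4th -> 3."""
    p = sorted(positions)
    lookup = {frozenset({(p[0], p[1]), (p[2], p[3])}): 1,
              frozenset({(p[0], p[2]), (p[1], p[3])}): 2,
              frozenset({(p[0], p[3]), (p[1], p[2])}): 3}
    return lookup[frozenset(tuple(sorted(x)) for x in pairing)]


def classify_isomer(disulfides, cys_positions=(4, 7, 12, 15)) -> IsomerLabel:
    """Assign a pairing of four cysteines to isomer 1/2/3.

    For guanylin numbering (4, 7, 12, 15): {(4,7),(12,15)} is isomer 1,
    {(4,12),(7,15)} isomer 2 (the biologically active form), and
    {(4,15),(7,12)} isomer 3.  A single bond yields ``partial`` with the
    unique isomer it commits to; the empty set yields ``none``.
    """
    positions = sorted(cys_positions)
    if len(positions) != 4:
        raise ConfigError("isomer classification is defined for four cysteines")
    pairs = {tuple(sorted(p)) for p in disulfides}
    used: set[int] = set()
    for a, b in pairs:
        if a not in positions or b not in positions:
            raise TopologyError(f"pair ({a},{b}) outside cysteine positions")
        if a in used or b in used or a == b:
            raise TopologyError(f"cysteine reused in pairing {sorted(pairs)}")
        used.update((a, b))
    if not pairs:
        return IsomerLabel(label="none")
    if len(pairs) == 2:
        idx = _isomer_index(pairs, positions)
        return IsomerLabel(label=f"isomer{idx}", pairing=frozenset(pairs))
    # one bond: completion is forced (the two free cysteines must pair)
    free = tuple(sorted(set(positions) - used))
    full = pairs | {free}
    idx = _isomer_index(full, positions)
    return IsomerLabel(
        label="partial", pairing=frozenset(pairs), committed=f"isomer{idx}"
    )


# ---------------------------------------------------------------------------
# Kinetic footprint
# ---------------------------------------------------------------------------

def kinetic_footprint(
    event_logs: dict[str, list[BondEvent]] | list[list[BondEvent]],
    cys_positions=(4, 7, 12, 15),
) -> tuple[pd.DataFrame, dict]:
    """First/second disulfide formation times per trajectory.

    Returns a table (trajectory, t_first, t_second, isomer) in ps, where
    ``t_second`` is NaN for runs that formed only one bond, plus a summary
    with mean times and isomer fractions (over completed runs and, using
    single-bond commitment, over all bond-forming runs).
    """
    if isinstance(event_logs, dict):
        items = list(event_logs.items())
    else:
        items = [(str(i), log) for i, log in enumerate(event_logs)]
    rows = []
    for name, log in items:
        formed = sorted(
            (e for e in log if e.kind == "formed"), key=lambda e: e.trigger_time
        )
        pairs = {tuple(sorted(e.residues)) for e in formed}
        lab = classify_isomer(pairs, cys_positions) if pairs else IsomerLabel("none")
        rows.append(
            {
                "trajectory": name,
                "t_first": formed[0].trigger_time if formed else np.nan,
                "t_second": formed[1].trigger_time if len(formed) > 1 else np.nan,
                "isomer": lab.label,
                "committed": lab.committed
                if lab.label == "partial"
                else (lab.label if lab.label.startswith("isomer") else None),
            }
        )
    df = pd.DataFrame(rows)
    complete = df[df["isomer"].str.startswith("isomer")]
    committed = df[df["committed"].notna()]
    summary = {
        "mean_t_first": float(df["t_first"].mean()),
        "mean_t_second": float(df["t_second"].mean()),
        "isomer_fractions": (
            complete["isomer"].value_counts(normalize=True).to_dict()
        ),
        "committed_fractions": (
            committed["committed"].value_counts(normalize=True).to_dict()
        ),
        "n_trajectories": len(df),
        "n_complete": int(len(complete)),
    }
    return df, summary


# ---------------------------------------------------------------------------
# Ensemble RMSD
# ---------------------------------------------------------------------------

def _coords(obj) -> np.ndarray:
    return obj.positions if isinstance(obj, Frame) else np.asarray(obj, dtype=float)


def superpose(mobile, reference) -> np.ndarray:
    """Optimal rigid-body superposition (rotation + translation, no scale)
    of ``mobile`` onto ``reference``; returns transformed coordinates."""
    a = _coords(mobile)
    b = _coords(reference)
    if a.shape != b.shape:
        raise GeometryError("conformer atom counts differ")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    rot, _ = Rotation.align_vectors(b - cb, a - ca)
    return rot.apply(a - ca) + cb


def pairwise_rmsd(a, b) -> float:
    """RMSD after optimal superposition, Å."""
    a = _coords(a)
    moved = superpose(a, b)
    return float(np.sqrt(((moved - _coords(b)) ** 2).sum(axis=1).mean()))


def ensemble_rmsd(conformers, selection=None, max_iter=50, tol=1e-10):
    """Coordinate spread of an ensemble, Å.

    Each conformer is iteratively superposed onto the evolving mean
    structure; the ensemble RMSD is the RMS of the per-conformer RMSDs to
    that mean.  Also returns the full pairwise RMSD matrix.
    """
    coords = [np.asarray(_coords(c), dtype=float) for c in conformers]
    if selection is not None:
        sel = np.asarray(selection, dtype=int)
        coords = [c[sel] for c in coords]
    if len(coords) < 2:
        raise GeometryError("ensemble RMSD requires at least two conformers")
    shape = coords[0].shape
    if any(c.shape != shape for c in coords):
        raise GeometryError("conformer atom counts differ")
    aligned = [c - c.mean(axis=0) for c in coords]
    mean = aligned[0].copy()
    for _ in range(max_iter):
        aligned = [superpose(c, mean) for c in aligned]
        new_mean = np.mean(aligned, axis=0)
        if np.max(np.abs(new_mean - mean)) < tol:
            mean = new_mean
            break
        mean = new_mean
    devs = [np.sqrt(((c - mean) ** 2).sum(axis=1).mean()) for c in aligned]
    e_rmsd = float(np.sqrt(np.mean(np.square(devs))))
    m = len(coords)
    mat = np.zeros((m, m))
    for i, j in combinations(range(m), 2):
        mat[i, j] = mat[j, i] = pairwise_rmsd(coords[i], coords[j])
    return e_rmsd, mat


def lowest_pairwise_rmsd(ensemble_a, ensemble_b, selection=None) -> float:
    """Minimum RMSD over all cross-ensemble conformer pairs."""
    ca = [_coords(c) for c in ensemble_a]
    cb = [_coords(c) for c in ensemble_b]
    if selection is not None:
        sel = np.asarray(selection, dtype=int)
        ca = [c[sel] for c in ca]
        cb = [c[sel] for c in cb]
    return min(pairwise_rmsd(a, b) for a in ca for b in cb)


# ---------------------------------------------------------------------------
# NOE violations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NOERestraint:
    """An experimental interproton distance bound.

    Groups are sets of ``residue:atom`` selectors (1-based residues; the
    atom part may carry ``*``/``?`` wildcards for unresolved, equivalent
    protons).  A group with several atoms is collapsed by the r⁻⁶ sum over
    all inter-group atom pairs before comparison with the bounds.
    """

    group_a: frozenset
    group_b: frozenset
    r_low: float
    r_high: float

    def __post_init__(self):
        if not (0 < self.r_low <= self.r_high):
            raise ConfigError("NOE bounds must satisfy 0 < r_low <= r_high")
        if not self.group_a or not self.group_b:
            raise ConfigError("NOE groups must be non-empty")


class StructureView:
    """Selector resolution over named coordinates.

    Built either from a ``{"res:atom": xyz}`` mapping or from a topology +
    frame (atoms named by their bead labels, residues 1-based).
    """

    def __init__(self, atoms: dict[str, np.ndarray]):
        self._atoms = {k: np.asarray(v, dtype=float) for k, v in atoms.items()}

    @classmethod
    def from_frame(cls, topology: Topology, frame: Frame) -> "StructureView":
        atoms = {}
        for p in range(topology.n_particles):
            key = f"{topology.particle_residue[p] + 1}:{topology.particle_names[p]}"
            atoms[key] = frame.positions[p]
        return cls(atoms)

    def resolve(self, selector: str) -> list[np.ndarray]:
        if ":" not in selector:
            raise ConfigError(f"selector {selector!r} is not residue:atom")
        res, atom = selector.split(":", 1)
        hits = [
            xyz
            for key, xyz in self._atoms.items()
            if key.split(":", 1)[0] == res
            and fnmatch.fnmatchcase(key.split(":", 1)[1], atom)
        ]
        if not hits:
            raise ConfigError(f"selector {selector!r} resolves to no atom")
        return hits


def _effective_distance(view: StructureView, restraint: NOERestraint) -> float:
    """r = (sum over equivalent pairs of r_i^-6)^(-1/6)."""
    xa = [x for sel in sorted(restraint.group_a) for x in view.resolve(sel)]
    xb = [x for sel in sorted(restraint.group_b) for x in view.resolve(sel)]
    inv6 = 0.0
    for a in xa:
        for b in xb:
            r = float(np.linalg.norm(a - b))
            if r <= 0:
                raise GeometryError("coincident atoms in NOE groups")
            inv6 += r ** -6
    return inv6 ** (-1.0 / 6.0)


def noe_violation(coords, restraints) -> tuple[np.ndarray, float]:
    """Per-restraint distance deviations and their mean, Å.

    The deviation is zero when the effective distance lies inside the NOE
    range, (r − r_high) above it and (r_low − r) below it; the per-restraint
    deviations are combined linearly and normalised by the restraint count.
    """
    view = coords if isinstance(coords, StructureView) else StructureView(coords)
    if not restraints:
        raise ConfigError("no NOE restraints given")
    devs = np.zeros(len(restraints))
    for i, rest in enumerate(restraints):
        r = _effective_distance(view, rest)
        if r > rest.r_high:
            devs[i] = r - rest.r_high
        elif r < rest.r_low:
            devs[i] = rest.r_low - r
    return devs, float(devs.mean())


# ---------------------------------------------------------------------------
# S–S distance series and box geometry
# ---------------------------------------------------------------------------

def ss_distance_series(frames, topology: Topology) -> dict[tuple[int, int], np.ndarray]:
    """Per-pair time series of sulfur–sulfur distances (Å), one series per
    reactive or bonded pair, keyed by the canonical (sorted) pair."""
    pairs = sorted(set(topology.reactive_pairs()) | topology.disulfides)
    out: dict[tuple[int, int], np.ndarray] = {}
    for pair in pairs:
        key = ordered_pair(*pair)
        out[key] = np.array([f.distance(*key) for f in frames])
    return out


def truncated_octahedron_diameter(edge_length: float) -> float:
    """Diameter of the inscribed sphere (= unit-cell parameter) of a
    truncated octahedron with edge length l: d = a = l sqrt(6)."""
    if edge_length <= 0:
        raise GeometryError("edge length must be positive")
    return edge_length * np.sqrt(6.0)
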