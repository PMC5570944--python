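"""Seeded generators of coarse-grained test systems.

The flagship fixture is a guanylin-like 15-residue chain with reactive
cysteines at positions 4, 7, 12 and 15 — one backbone bead per residue
(3.8 Å virtual bonds, the Cα–Cα spacing of a trans peptide) plus a sulfur
bead hung 1.8 Å off each cysteine.  Chains are self-avoiding random walks:
a clash filter rejects placements that put non-bonded beads closer than
twice the bead radius, standing in for the energy screening a real
unfolded-ensemble generator would perform.

All generators are pure functions of their seed and spec.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GenerationError, ConfigError
from .model_core import (
    GENERIC,
    RCYS,
    AngleTerm,
    BondTerm,
    Frame,
    Topology,
)

__all__ = ["ChainSpec", "random_chain", "guanylin_chain", "two_bead_system",
           "four_bead_css_c", "GUANYLIN_POSITIONS"]

#: 1-based cysteine positions of mature guanylin.
GUANYLIN_POSITIONS = (4, 7, 12, 15)

BACKBONE_MASS = 110.0   # amu, average residue
SULFUR_MASS = 32.0      # amu
CA_S_BOND = 1.8         # Å
BOND_K = 100.0          # kcal/mol/Å² (E = k dx²)
ANGLE_K = 2.0           # kcal/mol/rad², weak backbone stiffness
ANGLE_T0 = 120.0        # degrees
BEAD_RADIUS = 1.8       # Å; clash filter keeps non-bonded beads > 2x apart


@dataclass(frozen=True)
class ChainSpec:
    n_residues: int = 15
    reactive_positions: tuple[int, ...] = GUANYLIN_POSITIONS  # 1-based
    bond_length: float = 3.8  # Å
    seed: int = 0

    def __post_init__(self):
        pos = self.reactive_positions
        if len(set(pos)) != len(pos):
            raise ConfigError("reactive positions must be distinct")
        for p in pos:
            if not 1 <= p <= self.n_residues:
                raise ConfigError(f"reactive position {p} outside chain")


def chain_topology(residue_labels: list[str], bond_length: float = 3.8) -> Topology:
    """Build the standard CG chain topology from residue type codes.

    Every RCYS/XCYS residue gets a sulfur bead (appended after the
    backbone beads, in residue order); only RCYS sulfurs are reactive.
    """
    from .model_core import XCYS

    n = len(residue_labels)
    names = ["CA"] * n
    residue = list(range(n))
    masses = [BACKBONE_MASS] * n
    bonds = [BondTerm(i, i + 1, BOND_K, bond_length) for i in range(n - 1)]
    angles = [AngleTerm(i - 1, i, i + 1, ANGLE_K, ANGLE_T0) for i in range(1, n - 1)]
    site_anchor: dict[int, int] = {}
    reactive_sites: list[int] = []
    for r, label in enumerate(residue_labels):
        if label not in (RCYS, XCYS):
            continue
        s_index = len(names)
        names.append("SG")
        residue.append(r)
        masses.append(SULFUR_MASS)
        bonds.append(BondTerm(r, s_index, BOND_K, CA_S_BOND))
        site_anchor[s_index] = r
        if label == RCYS:
            reactive_sites.append(s_index)
    topo = Topology(
        residue_labels=list(residue_labels),
        particle_names=names,
        particle_residue=residue,
        masses=np.array(masses, dtype=float),
        bonds=bonds,
        angles=angles,
        reactive_sites=reactive_sites,
        site_anchor=site_anchor,
    )
    topo.refresh_mask()
    topo.validate()
    return topo


def _build_topology(spec: ChainSpec) -> Topology:
    reactive = set(spec.reactive_positions)
    labels = [RCYS if (i + 1) in reactive else GENERIC for i in range(spec.n_residues)]
    return chain_topology(labels, spec.bond_length)


def random_chain(spec: ChainSpec) -> tuple[Topology, Frame]:
    """Self-avoiding random-walk chain, deterministic per seed.

    Raises :class:`GenerationError` if no clash-free placement is found
    after bounded retries (pathological specs only).
    """
    topo = _build_topology(spec)
    excl = topo.exclusions()
    min_sep = 2.0 * BEAD_RADIUS
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues

    for _attempt in range(100):
        pos = np.zeros((topo.n_particles, 3))
        ok = True
        # backbone walk
        for i in range(1, n):
            for _try in range(200):
                step = rng.standard_normal(3)
                step *= spec.bond_length / np.linalg.norm(step)
                cand = pos[i - 1] + step
                if _clear(cand, pos[:i], i, excl, min_sep):
                    pos[i] = cand
                    break
            else:
                ok = False
                break
        if not ok:
            continue
        # sulfur beads
        for s, anchor in sorted(topo.site_anchor.items()):
            for _try in range(200):
                d = rng.standard_normal(3)
                d *= CA_S_BOND / np.linalg.norm(d)
                cand = pos[anchor] + d
                if _clear(cand, pos[:s], s, excl, min_sep):
                    pos[s] = cand
                    break
            else:
                ok = False
                break
        if ok:
            pos -= pos[:n].mean(axis=0)  # centre in the reflective sphere
            frame = Frame(
                time=0.0,
                positions=pos,
                velocities=np.zeros_like(pos),
            )
            return topo, frame
    raise GenerationError(
        f"failed to place a clash-free chain for spec {spec} after 100 restarts"
    )


def _clear(cand, placed, idx, excl, min_sep):
    for j in range(placed.shape[0]):
        pair = (j, idx) if j < idx else (idx, j)
        if pair in excl:
            continue
        if np.linalg.norm(cand - placed[j]) < min_sep:
            return False
    return True


def guanylin_chain(seed: int = 0) -> tuple[Topology, Frame]:
    """The guanylin-like preset: 15 residues, reactive sites at 4, 7, 12, 15."""
    return random_chain(ChainSpec(seed=seed))


def two_bead_system(separation: float = 2.5) -> tuple[Topology, Frame]:
    """Two free reactive sulfur beads `separation` Å apart on the x axis.

    Minimal system for capture detection and distance-ramp tests.
    """
    topo = Topology(
        residue_labels=[RCYS, RCYS],
        particle_names=["SG", "SG"],
        particle_residue=[0, 1],
        masses=np.array([SULFUR_MASS, SULFUR_MASS]),
        reactive_sites=[0, 1],
        site_anchor={},
    )
    topo.refresh_mask()
    pos = np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]])
    return topo, Frame(time=0.0, positions=pos, velocities=np.zeros_like(pos))


def four_bead_css_c(
    ss_distance: float = 2.5,
    angle: float = 103.7,
    dihedral: float = 90.0,
) -> tuple[Topology, Frame]:
    """C-S-S-C toy: two cysteine backbone beads, each bonded to a sulfur.

    Particles are ordered C0, S1, S2, C3; geometry is built with the given
    S–S distance, C-S-S angles (both equal) and C-S-S-C dihedral, degrees.
    """
    theta = np.radians(angle)
    phi = np.radians(dihedral)
    s1 = np.array([0.0, 0.0, 0.0])
    s2 = np.array([ss_distance, 0.0, 0.0])
    # C0: angle(C0, S1, S2) = angle, in the xy plane
    c0 = s1 + CA_S_BOND * np.array([np.cos(theta), np.sin(theta), 0.0])
    # C3: angle(S1, S2, C3) = angle, rotated about the S-S axis by the dihedral
    c3 = s2 + CA_S_BOND * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
    )
    topo = Topology(
        residue_labels=[RCYS, RCYS],
        particle_names=["CA", "SG", "SG", "CA"],
        particle_residue=[0, 0, 1, 1],
        masses=np.array([BACKBONE_MASS, SULFUR_MASS, SULFUR_MASS, BACKBONE_MASS]),
        bonds=[BondTerm(0, 1, BOND_K, CA_S_BOND), BondTerm(2, 3, BOND_K, CA_S_BOND)],
        reactive_sites=[1, 2],
        site_anchor={1: 0, 2: 3},
    )
    topo.refresh_mask()
    pos = np.stack([c0, s1, s2, c3])
    return topo, Frame(time=0.0, positions=pos, velocities=np.zeros_like(pos))
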