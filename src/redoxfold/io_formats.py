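"""File formats: PDB subset, XYZ trajectories, config, NOE tables, logs.

External files use 1-based residue numbering (the PDB convention);
particle indices are 0-based everywhere inside the package — the
conversion is confined to this module.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.PDB import PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder
from Bio.PDB.PDBIO import PDBIO

from .analysis import NOERestraint
from .errors import ConfigError, ParseError
from .fixtures import ChainSpec, chain_topology, guanylin_chain, random_chain
from .model_core import (
    GENERIC,
    RCYS,
    XCYS,
    BondEvent,
    ControllerConfig,
    Frame,
    RampSchedule,
    ReductionConfig,
    Topology,
)

__all__ = [
    "read_pdb_subset",
    "write_pdb",
    "write_xyz_trajectory",
    "read_xyz_trajectory",
    "read_config",
    "read_noe_table",
    "write_event_log",
    "read_event_log",
    "RunManifest",
    "build_system",
]

_RESNAME = {GENERIC: "ALA", RCYS: "CYR", XCYS: "CYX"}
_LABEL = {"CYR": RCYS, "CYX": XCYS}


# ---------------------------------------------------------------------------
# PDB subset
# ---------------------------------------------------------------------------

def _prevalidate_pdb(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")) and len(line) >= 54:
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                    int(line[22:26])
                except ValueError as exc:
                    raise ParseError(f"malformed ATOM record: {exc}", line=lineno)


def read_pdb_subset(path) -> tuple[Topology, list[Frame]]:
    """Import CA and SG atoms from a PDB file.

    Residues named CYR become reactive cysteines, CYX disulfide-bonded
    ones, everything else generic backbone beads.  Multi-model files yield
    one conformer per model (velocities zero).  Formed-disulfide
    connectivity is not recoverable from coordinates alone and is left
    empty.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    _prevalidate_pdb(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("import", str(path))
    models = list(structure.get_models())
    if not models:
        raise ParseError("PDB file contains no models")

    # topology from the first model
    residues = [r for r in models[0].get_residues() if "CA" in r]
    if not residues:
        raise ParseError("no CA atoms found")
    labels = []
    for res in residues:
        name = res.get_resname().strip()
        if name in _LABEL and "SG" in res:
            labels.append(_LABEL[name])
        else:
            labels.append(GENERIC)
    topology = chain_topology(labels)

    frames = []
    for model in models:
        mres = [r for r in model.get_residues() if "CA" in r]
        if len(mres) != len(residues):
            raise ParseError("models differ in residue count")
        pos = np.zeros((topology.n_particles, 3))
        for i, res in enumerate(mres):
            pos[i] = res["CA"].get_coord()
        for s_index, anchor in sorted(topology.site_anchor.items()):
            res = mres[anchor]
            if "SG" not in res:
                raise ParseError(
                    f"residue {anchor + 1} lacks the SG atom present in model 1"
                )
            pos[s_index] = res["SG"].get_coord()
        frames.append(
            Frame(time=0.0, positions=pos, velocities=np.zeros_like(pos))
        )
    return topology, frames


def write_pdb(frames, topology: Topology, path) -> None:
    """Write one or more conformers as a (multi-model) PDB subset file."""
    if isinstance(frames, Frame):
        frames = [frames]
    builder = StructureBuilder()
    builder.init_structure("redoxfold")
    for m, frame in enumerate(frames):
        builder.init_model(m)
        builder.init_chain("A")
        builder.init_seg("    ")
        for r, label in enumerate(topology.residue_labels):
            builder.init_residue(_RESNAME[label], " ", r + 1, " ")
            builder.init_atom(
                "CA",
                np.asarray(frame.positions[r], dtype=np.float32),
                0.0, 1.0, " ", " CA ", r * 2 + 1, element="C",
            )
        for s_index, anchor in sorted(topology.site_anchor.items()):
            # re-enter the residue to append its sulfur bead
            chain = builder.chain
            res = chain[(" ", anchor + 1, " ")]
            builder.residue = res
            builder.init_atom(
                "SG",
                np.asarray(frame.positions[s_index], dtype=np.float32),
                0.0, 1.0, " ", " SG ", 0, element="S",
            )
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


# ---------------------------------------------------------------------------
# XYZ trajectory + sidecar index
# ---------------------------------------------------------------------------

def write_xyz_trajectory(frames, topology: Topology, path, index_path=None) -> None:
    """Plain multi-frame XYZ (element = bead name) plus a CSV index with
    the frame times."""
    path = Path(path)
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"{topology.n_particles}\n")
            fh.write(f"t= {float(frame.time)!r} ps\n")
            for p in range(topology.n_particles):
                x, y, z = (float(v) for v in frame.positions[p])
                fh.write(f"{topology.particle_names[p]} {x!r} {y!r} {z!r}\n")
    if index_path is not None:
        pd.DataFrame(
            {"frame": range(len(frames)), "time_ps": [f.time for f in frames]}
        ).to_csv(index_path, index=False)


def read_xyz_trajectory(path) -> list[Frame]:
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError("expected atom count", line=i + 1)
        comment = lines[i + 1]
        t = float(comment.split()[1])
        pos = np.zeros((n, 3))
        for p in range(n):
            parts = lines[i + 2 + p].split()
            pos[p] = [float(v) for v in parts[1:4]]
        frames.append(Frame(time=t, positions=pos, velocities=np.zeros_like(pos)))
        i += 2 + n
    return frames


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

_SYSTEM_KEYS = {"preset", "pdb", "n_residues", "reactive_positions",
                "bond_length", "chain_seed"}
_CONTROLLER_KEYS = {
    "capture_radius", "accept_prob", "segment_length", "frame_interval",
    "lj_mode", "mask_onset", "stage_lengths", "seed",
}
_RAMP_KEYS = {"n_steps", "step_duration"}
_ENGINE_KEYS = {"dt", "gamma", "temperature", "sphere_radius"}
_RESTRAINT_KEYS = {
    "ss_target", "ss_force_constant", "angle_target", "angle_force_constant",
    "dihedral_target_abs", "dihedral_force_constant",
}
_REDUCTION_KEYS = {"enabled", "base_prob", "exposure_fn"}


def _check_keys(section: str, given: dict, allowed: set):
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in [{section}]: {', '.join(sorted(unknown))}"
        )


def read_config(path) -> tuple[dict, ControllerConfig]:
    """Read a YAML run configuration.

    Returns the system description (passed to :func:`build_system`) and a
    fully populated :class:`ControllerConfig`.  Unknown keys are rejected;
    all defaults are those documented on the config dataclasses.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(
        "root", raw,
        {"system", "controller", "ramp", "engine", "restraints", "reduction"},
    )
    system = raw.get("system") or {"preset": "guanylin"}
    _check_keys("system", system, _SYSTEM_KEYS)
    controller = raw.get("controller") or {}
    _check_keys("controller", controller, _CONTROLLER_KEYS)
    ramp = raw.get("ramp") or {}
    _check_keys("ramp", ramp, _RAMP_KEYS)
    engine = raw.get("engine") or {}
    _check_keys("engine", engine, _ENGINE_KEYS)
    restraints = raw.get("restraints") or {}
    _check_keys("restraints", restraints, _RESTRAINT_KEYS)
    reduction = raw.get("reduction") or {}
    _check_keys("reduction", reduction, _REDUCTION_KEYS)

    kwargs = dict(controller)
    if "stage_lengths" in kwargs:
        kwargs["stage_lengths"] = tuple(float(v) for v in kwargs["stage_lengths"])
    kwargs.update(engine)
    kwargs.update(restraints)
    if ramp:
        kwargs["ramp"] = RampSchedule(**ramp)
    if reduction:
        kwargs["reduction"] = ReductionConfig(**reduction)
    try:
        config = ControllerConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc))
    return system, config


def build_system(system: dict, seed: int | None = None) -> tuple[Topology, Frame]:
    """Materialise the system section of a config: a preset, a synthetic
    chain spec, or a PDB subset file."""
    preset = system.get("preset", "guanylin")
    chain_seed = int(system.get("chain_seed", seed if seed is not None else 0))
    if "pdb" in system:
        topo, frames = read_pdb_subset(system["pdb"])
        return topo, frames[0]
    if preset == "guanylin":
        return guanylin_chain(seed=chain_seed)
    if preset == "chain":
        spec = ChainSpec(
            n_residues=int(system.get("n_residues", 15)),
            reactive_positions=tuple(system.get("reactive_positions", (4, 7, 12, 15))),
            bond_length=float(system.get("bond_length", 3.8)),
            seed=chain_seed,
        )
        return random_chain(spec)
    raise ConfigError(f"unknown system preset {preset!r}")


# ---------------------------------------------------------------------------
# NOE restraint tables
# ---------------------------------------------------------------------------

def read_noe_table(path) -> list[NOERestraint]:
    """Whitespace/tab-separated table: group_a group_b r_low r_high.

    Each group is one selector (``residue:atom``, wildcards allowed) or
    several joined by commas.  Lines starting with ``#`` are comments.
    """
    try:
        df = pd.read_csv(
            path, sep=r"\s+", comment="#", header=None,
            names=["group_a", "group_b", "r_low", "r_high"],
        )
    except Exception as exc:
        raise ParseError(f"cannot read NOE table: {exc}")
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                NOERestraint(
                    group_a=frozenset(str(row["group_a"]).split(",")),
                    group_b=frozenset(str(row["group_b"]).split(",")),
                    r_low=float(row["r_low"]),
                    r_high=float(row["r_high"]),
                )
            )
        except (ValueError, ConfigError) as exc:
            raise ParseError(f"bad NOE restraint: {exc}", line=int(idx) + 1)
    return out


# ---------------------------------------------------------------------------
# Event logs (JSON lines)
# ---------------------------------------------------------------------------

def write_event_log(events, path) -> None:
    with open(path, "w") as fh:
        for e in events:
            fh.write(json.dumps(e.to_dict()) + "\n")


def read_event_log(path) -> list[BondEvent]:
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                events.append(BondEvent.from_dict(json.loads(line)))
            except (json.JSONDecodeError, KeyError) as exc:
                raise ParseError(f"bad event record: {exc}", line=lineno)
    return events


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Provenance record of a run: config snapshot, seed, stage boundaries
    and the checksums of every output file."""

    config: dict
    seed: int
    version: str
    stage_boundaries: tuple[float, float, float]
    files: dict[str, str] = dataclasses.field(default_factory=dict)

    def add_file(self, path) -> None:
        path = Path(path)
        self.files[path.name] = _sha256(path)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            config=d["config"],
            seed=d["seed"],
            version=d["version"],
            stage_boundaries=tuple(d["stage_boundaries"]),
            files=d["files"],
        )

    def verify(self, directory) -> list[str]:
        """Return the names of files whose checksum no longer matches."""
        directory = Path(directory)
        bad = []
        for name, digest in self.files.items():
            target = directory / name
            if not target.exists() or _sha256(target) != digest:
                bad.append(name)
        return bad
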