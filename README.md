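# redoxfold

Reactive molecular dynamics for **oxidative folding** — peptide folding
coupled to the formation of disulfide (S–S) bonds — on a self-contained
coarse-grained Langevin engine.

Conventional MD force fields have no facility for making or breaking
chemical bonds, so peptides like guanylin (15 residues, four cysteines,
three possible disulfide isomers) cannot be folded to their oxidized
forms in silico.  `redoxfold` implements a perturbation-free protocol
that adds this capability to an otherwise standard simulation:

1. The Lennard-Jones repulsion between pairs of *reactive* cysteine
   sulfurs is masked at short range, so two thiols can diffuse within a
   capture radius r_c = 2.5 Å of each other.
2. Each contact frame passes a rejection-sampling gate with probability
   p₀ (p₀ = 1: every encounter is productive; p₀ = 0.001 slows bonding
   to well below the chain's conformational dynamics).
3. On acceptance, the trajectory is rewound bitwise to the crossing
   frame, and artificial restraints imitating the disulfide — S–S
   distance αk_d(r_SS − r⁰_SS)² with k_d = 166 kcal/mol/Å² and
   r⁰_SS = 2.038 Å, C-S-S/S-S-C angles toward 103.7°, one C-S-S-C
   dihedral — are ramped up step-wise, α = k/200 every 10 ps.
4. The restraints are then replaced by an exactly equivalent permanent
   bond and the two cysteines become standard disulfide-bonded residues.

Away from close thiol encounters the system evolves under the exact,
unmodified potential — bit for bit, which the test suite asserts.  An
optional reverse move reduces formed disulfides with a low probability
proportional to a solvent-exposure proxy.  Analysis tools cover isomer
classification, kinetic footprints (first/second bond times), radius of
gyration, ensemble RMSD with optimal superposition, and NOE-restraint
violation scoring with r⁻⁶ averaging over equivalent protons.

Intended users: simulators studying disulfide-coupled folding pathways,
kinetic vs. thermodynamic control of isomer distributions, and protocol
development for reactive MD, at a scale where runs take seconds.

## Worked example

```bash
$ redoxfold run --seed 0 --out run0
INFO redoxfold: formed (7, 12) at t = 44.0 ps (r = 2.326 Å, 0 rejected draws)
INFO redoxfold: formed (4, 15) at t = 534.0 ps (r = 2.360 Å, 0 rejected draws)
status: complete; events: 2; outputs in run0
```

The 15-residue guanylin-like chain (reactive cysteines at positions 4,
7, 12, 15) formed its first disulfide C7–C12 44 ps into the folding
stage, triggered at an S–S distance of 2.326 Å (every trigger is ≤ the
2.5 Å capture radius), and the second bond C4–C15 490 ps later — first
bonds form quickly, second bonds take much longer because one bridge
sharply reduces the conformational freedom of the chain.  The pairing
{7-12, 4-15} is isomer 3.  `run0/` contains the event log
(`events.jsonl`), the trajectory (`traj.xyz` + index), the final
structure (`final.pdb`), per-segment restart files, and a manifest with
checksums.

```bash
$ redoxfold replay --out run0 --segment 0
segment 0: replay OK (100 frames, digest b02d1e5f9fb2…)
```

re-propagates a recorded segment from its restart file and verifies the
result is bitwise identical to the original — the same machinery the
controller uses to rewind to the capture frame.  Library use mirrors the
CLI:

```python
from redoxfold import ControllerConfig, guanylin_chain, run_oxidative_folding

topology, frame = guanylin_chain(seed=0)
result = run_oxidative_folding(topology, frame, ControllerConfig.desk(seed=0))
print(result.status, [(e.residues, e.trigger_time) for e in result.formed])
# complete [((7, 12), 44.0), ((4, 15), 534.0)]
```

## Layout

- `src/redoxfold/model_core.py` — topology, frames, restraints, events, config
- `src/redoxfold/forcefield.py`, `_kernels.py` — energies, forces, BAOAB
  Langevin propagation (numba-compiled kernels)
- `src/redoxfold/controller.py` — capture / gate / rewind / ramp / bond loop
- `src/redoxfold/analysis.py` — isomers, footprints, R_g, RMSD, NOE scores
- `src/redoxfold/fixtures.py` — seeded synthetic chains and minimal systems
- `src/redoxfold/io_formats.py`, `cli.py` — PDB/XYZ/config/log I/O and the
  `redoxfold` command

See `docs/methods.md` for the model, its assumptions, parameter
defaults, and known limitations.
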