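# Methods

## The model

`redoxfold` implements a perturbation-free reactive protocol for disulfide
bond formation during peptide folding, on a self-contained coarse-grained
(CG) Langevin engine.  The peptide is a chain of backbone beads (one per
residue, 3.8 Å virtual bonds) plus one sulfur bead hung 1.8 Å off each
cysteine backbone bead.  Reactive cysteines (residue code `RCYS`) model
deprotonated but net-neutral thiols that can bond in a barrier-free
fashion; once bonded, both residues become `XCYS` and behave as standard
disulfide-bonded cysteines.

Units are fixed package-wide: Å, ps, kcal/mol, K, amu, with
k_B = 0.0019872041 kcal/mol/K.

### Potential energy

- Bonds and angles are harmonic in the Amber convention E = k·Δ² (no ½).
  Backbone bonds k = 100 kcal/mol/Å², backbone angles k = 2 kcal/mol/rad²
  at 120° (a weak stiffness that keeps the disordered chain from
  degenerate overlaps without imposing secondary structure).
- Non-bonded pairs interact through a Lennard-Jones term in the r-min
  form ε((r₀/r)¹² − 2(r₀/r)⁶) with ε = 0.25 kcal/mol, r₀ = 4 Å — the
  sulfur–sulfur parameters of a standard protein force field, used
  uniformly for all beads — truncated (not shifted) at 10.5 Å.  1-2 and
  1-3 bonded neighbours are excluded.
- Harmonic dihedral terms (deviation on the shortest arc) exist only for
  formed disulfides.

### The reactive-pair mask

The pairwise LJ term between two reactive sulfurs is switched off at
short range: a masked pair feels nothing below the mask onset of 3.5 Å
and the unmodified potential beyond it.  The onset is where the LJ
repulsive wall would otherwise prevent the sulfurs from reaching the
capture radius; removing only the short-range part means that whenever
all reactive pairs are farther than 3.5 Å apart the system evolves under
*exactly* the standard potential — bit for bit, not approximately.  The
alternative mode `shrunk_r0` instead sets r₀ = 2 Å for reactive pairs
(the capture radius stays 2.5 Å in both modes).

## The oxidative-folding controller

A run has three stages: equilibration under the standard potential,
oxidative folding, and a conventional extension.  During folding the
trajectory advances in fixed segments (frames stored every 1 ps); after
each segment:

1. **Capture** — the earliest stored frame where any reactive S–S
   distance ≤ r_c = 2.5 Å is located.  Ties within one frame break by
   smallest distance, then lexicographically smallest pair (the tie-break
   is a package choice; determinism is required for replay).
2. **Gate** — each contact frame is accepted with probability p₀ drawn
   from a dedicated RNG stream (p₀ = 1: every encounter is productive;
   p₀ = 0.001 reproduces the reduced-reactivity protocol where roughly
   one contact frame in a thousand bonds).  The gate is evaluated once
   per stored frame per contact pair, making p₀ a per-picosecond
   probability.  Rejected draws are counted into the eventual bond event.
3. **Rewind** — the segment is re-propagated from its restart frame to
   the crossing frame and must reproduce it bitwise; any divergence is a
   fatal reproducibility error.
4. **Ramp** — artificial restraints imitating the disulfide are ramped
   from 1/n to 1 in n steps of one window each (default n = 200, 10-ps
   windows; α = k/n held constant within window k): an S–S distance
   restraint αk_d(r_SS − r⁰_SS)² with k_d = 166 kcal/mol/Å² and
   r⁰_SS = 2.038 Å, C-S-S and S-S-C angle restraints toward 103.7°
   (k = 68 kcal/mol/rad²), and one C-S-S-C dihedral restraint toward
   ±90° (k = 3.5 kcal/mol/rad²), the sign taken from the geometry at
   ramp start since the two minima are symmetric.  The restraints
   imitate the bond's nonbonded exclusions too: a zero-strength scaffold
   bond marks the nascent disulfide in the bond graph, so the S–S (1-2)
   and C⋯S (1-3) pairs are excluded during the ramp exactly as they will
   be afterwards.  Without this the uniform CG bead size leaves an
   anchor–sulfur LJ overlap that biases the ramped C-S-S angle several
   degrees open; with it, the hand-off below is exactly energy-neutral.
5. **Bond** — the restraints are replaced by permanent bonded terms with
   the same targets and full force constants, the pair leaves the
   reactive registry, its residues become `XCYS`, and every mask entry
   involving them is dropped.  Bonds form strictly one at a time; other
   reactive pairs stay masked during a ramp but cannot trigger capture
   until the next segment.

The formal ramp schedule starts at α(0) = 0, but the first *applied*
scale is α(1) = 1/n, matching a counter that starts at 1 — both
endpoints are asserted exactly in the tests.

An optional reverse step models reduction (e.g. by glutathione): at each
segment boundary every formed disulfide is reduced with probability
p_r × exposure(pair), where the exposure proxy is either uniform or a
buriedness estimate (inverse neighbour count around the S–S midpoint),
and reduction inverts the bonding mutation exactly.  p_r should be small
compared with the effective oxidation rate.

### Randomness and replay

Dynamics noise, gate decisions and reduction decisions use three
independent PCG64 streams spawned from the run seed, so gating never
perturbs the dynamics noise sequence.  Every stored frame carries the
dynamics RNG state; replaying any stretch of trajectory from a stored
frame is bitwise exact.  Gaussian noise is drawn outside the compiled
kernel in per-frame blocks, which is what makes the state capture cheap.

## Integrator

BAOAB Langevin splitting at dt = 0.002 ps, collision frequency
γ = 2 ps⁻¹, T = 293 K.  With γ = 0 the splitting reduces exactly to
velocity Verlet, giving a clean NVE limit (energy conservation to 1e-4
relative on a soft harmonic pair over 10⁴ steps); at γ > 0 the kinetic
temperature recovers the target within sampling error.  There are no
periodic boundaries (no solvent); a reflective sphere of radius 60 Å
keeps the chain from diffusing away.  Forces are the exact negative
energy gradient (finite-difference checked for every term type).  The LJ
truncation at 10.5 Å introduces a small discontinuity that a thermostat
at this coarse scale tolerates; it is not shifted so that published
parameter values keep their meaning.

## Synthetic systems

The generator produces self-avoiding random-walk chains (clash filter:
non-bonded beads at least two bead radii, 3.6 Å, apart) with sulfur
beads placed on collision-free random directions; all generators are
pure functions of seed and spec.  The flagship preset is a guanylin-like
15-residue chain with reactive cysteines at positions 4, 7, 12, 15,
whose three complete pairings define isomers 1–3 (isomer 2, pairing
{4-12, 7-15}, is the biologically active one).  The clash filter stands
in for the energy screening a real unfolded-ensemble generator performs.

What the CG fixture does *not* emulate: side chains, sequence-specific
sterics and conformational propensities, solvent structure and
electrostatics.  Passing tests therefore demonstrate the correctness of
the reactive protocol (capture, gating, replay, ramping, topology
mutation, perturbation-freeness) and the statistical machinery — not
that this CG chain reproduces published all-atom isomer distributions or
absolute kinetics, which required microseconds of explicit-solvent
sampling.  Relative features do carry over qualitatively: first bonds
form quickly, second bonds take much longer, and lowering p₀ slows
bonding less than proportionally because conducive conformers with S–S
distances fluctuating around 2–4 Å are long-lived.

## Analysis statistics

- Radius of gyration: mass-weighted RMS distance from the centre of mass.
- Kinetic footprint: per-trajectory first/second bond times plus isomer
  fractions; a single-bond trajectory is assigned the unique isomer its
  bond commits to (always unique with four cysteines).
- Ensemble RMSD: conformers are iteratively superposed (optimal rotation
  + translation, SVD-based) onto the evolving mean structure; the
  ensemble value is the RMS of per-conformer RMSDs to that mean (the
  mean-structure convention; the alternative mean-pairwise convention is
  not used).  Cross-ensemble comparison reports the lowest pairwise
  RMSD.  An independent quaternion (Horn) superposition serves as the
  test oracle.
- NOE violations: per restraint, zero inside [r_low, r_high], r − r_high
  above, r_low − r below; ambiguous (wildcard) proton groups are
  collapsed by r = (Σ r_i⁻⁶)^(−1/6) over all inter-group pairs before
  comparison; per-restraint deviations are combined linearly and divided
  by the restraint count ("violation per restraint").
- Box geometry: the inscribed-sphere diameter of a truncated octahedron
  with edge l is d = a = l√6.

## Problem sizes

The package defaults run at desk scale: the `desk` preset uses 50 ps
equilibration, a 5 ns folding cap, 50 ps extension, 100 ps segments and
a 50 × 2 ps ramp for the 15-residue fixture, completing a full folding
run in seconds.  The ramp-endpoint measurements (S–S distance and C-S-S
angle) always use the full protocol schedule of 200 × 10 ps windows on
the two- and four-bead fixtures.  The `published_scale` preset exposes the
published stage lengths (100 ns / 1 µs cap / 450 ns, 1 ns segments) for
users with the patience to match them.

## Known limitations

- The gate counts at most one accepted event per segment; multiple
  crossings in one segment defer to the next (bonds are serialized).
- Capture detection samples at the frame interval (1 ps); sub-frame
  excursions below r_c between stored frames are invisible, exactly as
  in a frame-based post-processing implementation.
- PDB import recovers reactive-site flags from residue names but not
  formed-disulfide connectivity; topology JSON and the event log carry
  that state.
- The dihedral restraint list for a real disulfide is richer than the
  single C-S-S-C term used here; targets and constants are configurable.
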