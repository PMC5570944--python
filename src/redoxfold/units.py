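"""Package-wide unit system and physical constants.

Units are fixed across the package: length in Å, time in ps, energy in
kcal/mol, temperature in K, mass in amu (g/mol).  Velocities are therefore
Å/ps and forces kcal/mol/Å.
"""

#: Boltzmann constant, kcal/mol/K.
KB = 0.0019872041

#: Converts an acceleration expressed as (kcal/mol/Å)/amu into Å/ps².
#: 1 kcal/mol/Å / 1 amu = 4184 J mol⁻¹ Å⁻¹ / 1e-3 kg mol⁻¹ = 418.4 Å/ps².
FORCE_TO_ACCEL = 418.4

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 293.0

#: Default Langevin collision frequency, ps⁻¹.
DEFAULT_GAMMA = 2.0

#: Default integration timestep, ps (2 fs).
DEFAULT_DT = 0.002


def kinetic_energy(masses, velocities):
    """Kinetic energy in kcal/mol for masses in amu, velocities in Å/ps."""
    import numpy as np

    v2 = np.sum(velocities * velocities, axis=-1)
    return 0.5 * float(np.dot(masses, v2)) / FORCE_TO_ACCEL


def kinetic_temperature(masses, velocities):
    """Instantaneous kinetic temperature (K) from equipartition, 3N dof."""
    n = len(masses)
    ke = kinetic_energy(masses, velocities)
    return 2.0 * ke / (3.0 * n * KB)
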