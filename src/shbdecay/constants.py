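"""Physical constants in the package's working units.

Working units throughout: energy in eV, length in Angstrom, time in fs,
mass in amu, temperature in K.  Kinetic energy of a particle of mass m
(amu) moving at v (A/fs) is 0.5 * m * v**2 * AMU_A2_FS2_TO_EV.
"""

#: Reduced Planck constant, eV*fs.
HBAR_EV_FS = 0.6582119569

#: Boltzmann constant, eV/K.
KB_EV_K = 8.617333262e-5

#: hc, eV*nm -- photon wavelength lambda = HC_EV_NM / E(eV).
HC_EV_NM = 1239.84193

#: One Rydberg in eV.
RYDBERG_EV = 13.605693

#: Conversion 1 amu * (A/fs)**2 -> eV.
AMU_A2_FS2_TO_EV = 103.642696562

#: Thermal energy k_B T at 300 K, eV.
KT_300K_EV = KB_EV_K * 300.0

#: One eV expressed as a wavenumber, cm^-1.
EV_TO_WAVENUMBER = 8065.543937
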