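"""Physical constants and unit conventions.

The whole package works in a fixed unit system chosen to match surface-science
force-field practice:

* energy      : eV
* length      : Angstrom
* charge      : elementary charge e
* mass        : amu
* time        : fs

With these choices the Coulomb prefactor is ``KE_COULOMB`` (eV*A/e^2) and the
conversion of an acceleration ``F/m`` from (eV/A)/amu into A/fs^2 is
``ACC_EV_A_AMU``.
"""

# Coulomb constant 1/(4 pi eps0) in eV*Angstrom/e^2
KE_COULOMB = 14.399645

# Boltzmann constant in eV/K
K_BOLTZMANN = 8.617333262e-5

# (eV/Angstrom)/amu -> Angstrom/fs^2
ACC_EV_A_AMU = 9.64853322e-3

# 1 amu*(A/fs)^2 in eV; kinetic energy [eV] = 0.5*m*v^2 * EV_PER_AMU_A2_FS2
EV_PER_AMU_A2_FS2 = 1.0 / ACC_EV_A_AMU
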