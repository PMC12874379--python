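# Per-element nonbonded parameters for the Morse pair law.
#   element  epsilon_eV  R_angstrom  charge_e
# epsilon: well depth of the homo-pair; R: half of the equilibrium pair
# distance (pair distance under Lorentz-Berthelot mixing is R_i + R_j).
# Values are standard published UFF van-der-Waals constants converted to eV
# (D_i * 0.0433641) and Angstrom (x_i / 2); default charges are zero and are
# normally overridden per structure (e.g. +-0.9 e for the NaCl slab ions).
H   0.001908  1.4430  0.0
C   0.004553  1.9255  0.0
N   0.002992  1.8300  0.0
O   0.002602  1.7500  0.0
Na  0.001301  1.4915  0.0
Cl  0.009844  1.9735  0.0
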