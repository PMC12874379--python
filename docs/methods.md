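# Methods

This note documents the model, the numerical choices and their rationale,
and what the synthetic fixtures do and do not establish.

## Model and assumptions

The substrate is **rigid and periodic in the surface plane**; its entire
interaction with any adsorbate is carried by three scalar fields sampled on
a regular grid over the surface unit cell:

* the two halves of the Morse pair potential under Lorentz–Berthelot mixing,
  stored as the factor sums P(r) = Σ_j √ε_j e^(−2α(|r−r_j|−R_j)) (Pauli) and
  L(r) = Σ_j √ε_j e^(−α(|r−r_j|−R_j)) (London). The √ε convention is forced
  by the geometric-mean mixing rule: the pair prefactor √(ε_iε_j) splits
  into a per-molecule-atom weight √ε_i and a per-substrate-atom factor √ε_j
  inside the sum, making the factorized assembly *algebraically identical*
  to the direct pair sum (verified to 1e-12 relative in the tests).
* the electrostatic potential V of the ionic substrate, solved in
  reciprocal space only (below).

A molecule atom with (ε_i, R_i, q_i) then costs three tricubic
interpolations regardless of how many substrate atoms or atom types exist.
The molecule's own energy (harmonic bonds/angles, threefold cosine
torsions, Morse + Coulomb nonbonded with 1-2/1-3 exclusions and full 1-4
terms) is evaluated by direct sum in real space with **no periodic images
of the molecule** — the adsorbate is a single object, not an artificially
periodic one.

Key global parameters (defaults; units eV, Å, e):

| parameter | default | meaning |
|---|---|---|
| α | 1.5 Å⁻¹ | Morse stiffness, one value for all pairs |
| r_cut | 17 Å | per-pair Morse truncation (plain cut; the discontinuity is ~ε·e^(−α·17) ≈ 1e-11 of ε, far below every error budget, so no shift is applied) |
| grid spacing | 0.1 Å | production spacing for NaCl(001) grids |
| k_e | 14.399645 eV·Å/e² | Coulomb constant |
| fit budget | 3000 iterations | B-spline coefficient fit cap |
| FIRE threshold | 1e-3 eV/Å (scans), 1e-4 eV/Å (sampling) | max-force convergence |

Per-element (ε, R) values ship as an editable text table
(`src/gridff/data/elements.dat`); they are standard published UFF van der
Waals constants converted to eV/Å and are external inputs, not results of
this package. Accuracy statements below are grid-vs-reference comparisons
and are insensitive to the particular table values.

## Electrostatics: reciprocal-space Poisson solve

The substrate charges are projected onto a 3D grid that extends the
simulation window with vacuum padding in z (default: 4 Å below the slab
bottom, 16 Å above the window top) and is treated as fully periodic. Each
point charge is spread as an **isotropic Gaussian of width σ = 0.25 Å**
evaluated analytically on the nodes (support 6σ, renormalized so each atom
contributes exactly its charge). The potential is then V(k) = 4π k_e
ρ(k)/k² with the k = 0 mode set to zero (tin-foil convention; the cell must
be neutral), and the window slice is cropped out for fitting.

Why a Gaussian rather than a narrow B-spline stencil: a 4-point spreading
of a raw point charge has order-unity aliasing at the mesh Nyquist
frequency, and the aliased k_z components do not decay with height above
the surface — the estimated error was of the same order as the 0.01 meV
electrostatics budget. The σ = 2.5·h Gaussian is effectively band-limited
(relative aliasing ~4e-14 at 0.1 Å spacing), and no deconvolution back to
point charges is needed because a Gaussian's external potential equals the
point-charge potential up to erfc(r/σ√2), which is < 1e-30 everywhere a
molecule can reach (≥ 12σ from the nuclei). The omitted real-space
residual is therefore not a correction this solver needs at its operating
spacing; measured against a fully converged real+reciprocal Ewald
summation, the interpolated potential energy of a unit charge 3–5 Å above
NaCl(001) deviates by ~3e-4 meV.

The Ewald reference itself is a textbook 3D real+reciprocal summation with
vacuum padding for slabs and auto-scaled cutoffs (tails ~1e-11); no dipole
correction is applied because every rocksalt fixture layer is individually
neutral (Na and Cl at the same z), so the slab has zero net dipole and the
laterally averaged far potential vanishes identically. Changing the
splitting parameter moves the potential by ~1e-13 eV.

## B-spline fit and evaluation

Cubic B-splines are not interpolating, so coefficients are fitted to make
the spline pass through the node values. The node-evaluation operator A is
symmetric positive definite and separable (per-axis stencil (1, 4, 1)/6,
spectrum in [1/3, 1] per axis, hence [1/27, 1] in 3D). The production
fitter is gradient descent on the quadratic form ½cᵀAc − yᵀc, i.e. damped
Richardson iteration c ← c + ω(y − Ac) with ω = 1.8 < 2/λ_max,
zero-initialized from the node values; worst-mode contraction is 0.93 per
step and in practice the NaCl fields reach RMS node residuals ~1e-7
within ≲ 100 iterations (cap 3000, gate 1e-5 — "RMS residual" here means
the root-mean-square of y − Ac over all nodes in the field's native
units). Descent on the least-squares functional ½‖Ac−y‖² was rejected: its
effective condition number (λ_max/λ_min)² = 729² makes 1e-5 unreachable in
thousands of iterations. An exact separable prefilter (FFT division along
periodic axes, banded tridiagonal solve along z) ships alongside as the
independent reference; both routes agree in interpolated values to < 1e-8.

Boundaries: periodic along the lateral axes, clamped (edge-replicated
coefficient) along z. The clamped edge has a boundary layer a few nodes
wide whose local error decays geometrically (~0.27 per node) into the
interior; the default window therefore keeps the physically accessible
region ≥ ~10 nodes away from the bottom edge (window bottom 0.5 Å vs.
closest approach ≥ 2 Å), and the fields at the top edge are already ~1e-8
of their contact values. Atoms above the window top get exactly zero
surface interaction (documented asymptotic — the lateral harmonics decay as
e^(−|g|z) with |g| ≥ 2π/4 Å⁻¹, i.e. below 1e-6 eV by ~9 Å); atoms below
the window bottom raise a domain error, never silent extrapolation.

Evaluation reads the 4×4×4 coefficient stencil (z fastest in memory) and
returns the value and the analytic gradient of the same polynomial. The
measured consequences: spline forces match finite differences to < 1e-6,
the work integral along paths equals ΔE, and a bound probe atom run NVE
with the spline backend drifts < 1e-4 eV over 1 ps.

## Scan drivers and sampling

Rigid scans translate the molecule as a rigid body. Relaxed pulls/drags
pin one anchor atom (hard position reset + force zeroing each step — the
simplest scheme consistent with restraining a single atom), displace it in
0.1 Å increments, and FIRE-relax the rest **warm-started from the previous
geometry**; points that hit the step cap are recorded as unconverged and
the scan continues. FIRE uses the standard parameter set (α_start 0.1,
f_inc 1.1, f_dec 0.5, N_min 5, f_α 0.99, dt_max = 10·dt_init) with
velocity zeroing whenever ⟨F|v⟩ < 0; the returned geometry is never higher
in energy than the start.

Langevin dynamics is leapfrog with multiplicative friction and
per-replica counter-based RNG streams (Philox keyed by replica seed), so a
trajectory is bitwise reproducible and independent of how many replicas
run alongside; γ = 0, T = 0 reduces to plain NVE leapfrog. Defaults
γ = 0.01–0.02 fs⁻¹, dt = 0.5 fs are stability/thermalization knobs, not
physical claims; equipartition of a free atom is verified to ~2%.

Minima hopping alternates n_md = 1000 Langevin steps at 300 K with FIRE
relaxation to 0.1 meV/Å per replica; converged geometries enter a
catalogue whose uniqueness test is greedy first-seen RMSD in the
**absolute surface frame** (threshold 0.1 Å, no superposition, no lattice
folding — a molecule on a translated or rotated site is a different
adsorption structure). Replicas re-thermalize from their own relaxed
geometry; re-seeding from scratch is a possible alternative restart policy,
but re-thermalization keeps each replica a continuous Markov chain and
matches the counters' saturation behaviour, so it is the default. The
total/unique counters are checkpointed once per cycle; the comparison
interval does not affect the final set.

## Synthetic fixtures: what they emulate and what they do not

The rocksalt slab generator reproduces the study substrate exactly as
specified (surface lattice constant 4.0 Å — one Na + one Cl per 4×4 Å
lateral cell per layer, interlayer spacing 4/√2 Å, ±0.9 e charges; 8×8×3 →
384 atoms, 20×20×3 → 2400), including a neutral nearest-neighbour vacancy
pair for defect studies. The probe molecules (rigid planar plate, flexible
zigzag chain, alternating C/O "polyol" chain) are deterministic, neutral,
and carry realistic UFF-scale nonbonded parameters and modest bonded
constants (bond k = 30 eV/Å², angle k = 3 eV/rad², torsion V = 0.02 eV) —
stand-ins chosen because the reference adsorbates' geometries and fitted
charges are not published inputs. Consequently all accuracy statements
(grid-vs-Ewald, grid-vs-direct-sum along rigid and relaxed scans) transfer
to real adsorbates, since they compare two routes to the *same* model
energy; absolute binding energies, barrier heights and defect
stabilization energies of specific molecules do **not** transfer and are
not claimed. The vertical-scan error budget is quoted for the production
protocol (0.1 Å scan step, planar probe): sampling the z axis mid-cell
instead raises the Morse-component error from ~3e-7 to ~2e-6 eV — the
interpolation error of an exponential at h = 0.1 Å, not a backend
disagreement.

## Problem sizes and numerical hygiene

The shipped tests and the acceptance script run on the NaCl unit cell
(40×40×116 window nodes), probes of 4–15 atoms, pulls of up to 188 points,
and minima hopping with a handful of replicas and cycles — sizes chosen so
the whole suite reproduces on a single CPU in minutes while exercising
every code path at the production grid spacing. Degenerate inputs are
rejected loudly: non-neutral cells (Ewald/Poisson), overlapping atoms
(< 1e-6 Å), grid nodes on nuclei (< 1e-3 Å), zero bond lengths,
out-of-domain evaluations. Known limitations: rigid substrate (no
polarization or deflection), pairwise-only interaction model, clamped-edge
boundary layer (keep the window generous), and memory growth for
nonperiodic supercell grids, which scale with the full defect cell rather
than the unit cell.
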