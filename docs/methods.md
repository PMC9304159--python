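# Methods

This note documents the models implemented in `oxoscope`, the conventions
and defaults they use, what the synthetic generators do and do not emulate,
and the design choices made where the design was genuinely open. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Units and constants

Records store energies in hartree, frequencies in cm⁻¹ (imaginary modes as
negative wavenumbers), coordinates in Å, dipoles in debye, Hessians in
hartree/bohr², masses in amu. Every cross-unit conversion goes through one
table (`oxoscope.constants`): 1 hartree = 627.5095 kcal/mol, 1 cm⁻¹ =
2.8591×10⁻³ kcal/mol, hc/k_B = 1.43877 cm·K, k_B/h = 2.08366×10¹⁰ s⁻¹K⁻¹,
1 e·Å = 4.80321 debye, 1 D·(V/Å) = 4.8032 kcal/mol, e/Å² = 14.3996 V/Å,
1 V/Å = 1.94469×10⁻² atomic field units. Where a conversion is pure CODATA
physics (translation/rotation partition functions, Hessian eigenvalue →
wavenumber) the factors are taken from `scipy.constants`.

Default atomic masses are those of the most abundant isotope, not standard
atomic weights, because isotope substitution (D, ¹⁸O) is a first-class
operation and mixed-weight defaults would contaminate shifts. Per-atom mass
overrides are always available.

## Record model and I/O

A `QCRecord` is one species' quantum-chemistry results: label, charge,
multiplicity (2S+1), single-point energy `e_high` (optionally the
optimization-level `e_low`), solvation and dispersion corrections,
frequencies and/or a Cartesian Hessian, dipole, per-atom spin densities and
a geometry. The on-disk format is YAML with a `format:` tag and an explicit
unit header, one species per file, so fixtures are hand-auditable; unknown
keys round-trip through `extra`. Validation enforces a symmetric 3N×3N
Hessian, positive masses, and spin-parity consistency of the multiplicity
with the electron count whenever charge and geometry make that derivable.
`e_solv`/`e_disp` distinguish *absent* (`None`) from *zero* so that an
assembly scheme demanding a component can fail loudly.

PDB structures are parsed with `gemmi` behind `read_pdb`, keeping
ATOM/HETATM records of the first model (overridable) and preferring blank
or `'A'` altlocs; residue numbering is preserved as read. Writing PDB and
mmCIF are out of scope.

## RRHO thermochemistry

`rrho` evaluates the rigid-rotor harmonic-oscillator partition functions at
(T, P), default 298.15 K and 1 atm:

- ZPE = ½ Σ hcνᵢ over real modes. Imaginary modes are excluded from every
  sum and counted; more than one raises a warning (the record is probably
  not a proper stationary point) but the computation proceeds.
- Vibrations: per mode θ = 1.43877·ν K; thermal energy Rθ/(e^{θ/T}−1),
  entropy R[(θ/T)/(e^{θ/T}−1) − ln(1−e^{−θ/T})]. Low modes enter as-is —
  no quasi-RRHO damping — matching the protocol the published barriers were
  produced with; a damped variant was deliberately not made the default.
- Translation (Sackur–Tetrode) and rotation require a geometry; without one
  only vibrational terms are returned, which cancels exactly in relative
  energies of same-composition species. Linearity is detected by a smallest
  moment-of-inertia eigenvalue below 1e-4 amu·Å² — robust for the diatomic
  fixtures. The symmetry number is fixed at 1: enzyme-model species have no
  symmetry and this matches common QC-code defaults.
- H_corr includes the PV term (ideal gas); G_corr = H_corr − T·S exactly.

Thermochemistry uses **unscaled** frequencies by default; scaling
(`scale_frequencies`, e.g. the 0.95 harmonic factor) is report-oriented and
applies to real modes only, leaving imaginary magnitudes untouched. The
¹⁸O stretch shift can be quoted unscaled or scaled; scaling commutes with
the mass ratio, so the scaled shift is exactly 0.95× the unscaled one, and
the analysis driver prints both.

Hessian-based frequencies mass-weight the Cartesian Hessian, project out
overall translation and rotation (orthonormalized mass-weighted vectors,
rank-detected so linear molecules lose five modes, nonlinear six), and
convert eigenvalues to signed wavenumbers. `isotope_frequencies` re-runs
this with substituted masses; the projection is rebuilt for the new masses.

## Composite energies

`assemble` builds E_total in kcal/mol from explicit components that sum
exactly: scheme `E+ZPE+solv` = 627.5095·E_high + ZPE + 627.5095·E_solv;
`E+ZPE+solv+disp` adds dispersion; `G` adds the thermal enthalpy beyond ZPE
and −T·S. A scheme that needs a component the record does not carry raises
an error naming it. The package default scheme is `E+ZPE+solv+disp`; the
relative-energy table reports that scale and the free-energy scale side by
side, mirroring the "energies (free energies)" convention of cluster-model
landscape figures.

## Kinetics

Eyring with transmission coefficient κ = 1 throughout; tunnelling enters
only through the Wigner factor, computed from the magnitude of the TS
imaginary wavenumber: Q_t = 1 + (hcν/k_BT)²/24. KIE_Wigner =
KIE_Eyring·Q_t,H/Q_t,D; a deuterated imaginary mode larger than the protio
one is unphysical for H transfer and triggers a warning, not an error.
`dg_from_rate`/`rate_from_dg` are exact inverses over ≥18 decades of k.

Branching assumes Curtin–Hammett conditions — a common, rapidly
equilibrating reactant feeding irreversible first steps — so fractions are
softmax(−ΔG‡/RT), shift-invariant and computed with the minimum barrier
subtracted for numerical stability. Free-energy barriers are used when
available, ΔE+ZPE otherwise, and the choice is recorded on the result.
Default temperature 298.15 K; comparison against the experimental rate uses
278.15 K (5 °C).

## Landscapes and selectivity

Stationary points carry role (Re, TS1_HA, IM1, TS2_reb, P), pathway
(C1R/C1S/C2R/C2S), spin multiplicity and model label. TS roles must show
exactly one imaginary mode when frequencies are present; minima none. One
reactant reference per (model, spin) slice anchors relative energies; the
reference row of the table is exactly zero. Several TSs may feed one
intermediate (both C1 abstractions lead to the same radical), so TS2
validation accepts an IM1 matching by pathway or by carbon.

Rate-determining-step selection takes the highest non-estimated TS of a
pathway; barriers obtained from constraint scans rather than located TSs
are stored as `estimated` points and excluded. Ties resolve toward the
earlier mechanistic step and are flagged — deterministic output over
silent arbitrariness.

The selectivity verdict sums Boltzmann fractions per carbon: > 0.9
"dominant", 0.5–0.9 "preferred", else "unselective" (ties at 1e-9 absolute
count as unselective). The thresholds encode the qualitative language the
field uses ("dominant product", "small amounts possible") and are
deliberately coarse; nothing downstream depends on their exact placement.

Group spin densities are plain sums over named disjoint atom-index sets
with the ungrouped remainder reported, so total spin is conserved under any
partition. The hydrogen-bond census runs either on D–H···A triples
(H···A ≤ d_max, default 2.5 Å; angle ≥ 120°) or, when no hydrogens are
resolved (crystal structures), in distance-only mode on D···A pairs.

## BDFE and field response

BDFE = G(R•) + G(H•) − G(RH), all on one assembly scheme (mixing schemes is
an error). The field model is first-order Stark: BDFE(F) = BDFE(0) −
(Δμ·u)·F with Δμ the homolysis dipole change and u a unit axis through the
centre of mass; a quadratic −½Δα·F² term is available when a polarizability
difference is supplied but is off by default — the qualitative axis-
dependent behaviour of interest is linear. Sign convention: positive F
points along +u; the convention is configurable by negating the grid, since
the original calculations' axis orientation is not recoverable from text.
Fields are sanity-bounded at |F| ≤ 1 V/Å. Crossing fields solve the linear
systems analytically; `weakest_bond_map` is an argmin over the grid with
linear-interpolated transition fields.

Gas-phase reference BDFEs (85.8/74.7 kcal/mol for C1–H/C2–H) require an
external DFT engine and appear in this package only as *inputs* to worked
examples; the solvated ordering is encoded only as an inequality (C1–H
weakest within a ~2 kcal/mol window) in synthetic fixtures.

## Protein electrostatics

Formal charges: Asp/Glu −1, Arg/Lys +1, His 0 unless explicitly flagged
protonated (+1); termini ignored. This matches the residue-tally convention
in which His is excluded from the charged count unless protonated. Charges
sit on side-chain representative atoms (Asp CG, Glu CD, Arg CZ, Lys NZ,
protonated His at the ND1/NE2 midpoint; centroid fallback), a standard
coarse placement that is documented and overridable. The dipole is
Σqᵢ(rᵢ−origin)·4.80321 debye — translation-invariant only for net-neutral
systems, so the origin is part of any reported moment for a charged
protein. The field is an unscreened vacuum Coulomb sum (optional uniform
dielectric divisor); this is direction-of-dipole reasoning, not
Poisson–Boltzmann, and is labelled as such. HETATM residues and
non-amino-acid het groups never enter the census. Census counting is
residue-identity based over unique (chain, resnum); any discrepancy against
published tallies on a real structure should be reported, not adjusted.

## Synthetic generators

`gen_harmonic_system` builds H = M^{1/2} W diag(λ) Wᵀ M^{1/2} with W an
orthonormal basis of the internal subspace mixed by a seeded random
rotation and λᵢ = (2πcνᵢ)²; translations and rotations are exactly null, so
the projected spectrum equals the prescription to eigensolver precision
(≪1e-6 cm⁻¹). Linear targets (3N−5) produce collinear geometries, nonlinear
(3N−6) seeded random ones.

`gen_landscape` realizes prescribed ΔE+ZPE and ΔG offsets exactly. All
records of a landscape share one set of base real modes (so shared thermal
terms cancel); each record carries six low-frequency "tuning" modes whose
wavenumber is solved (Brent) so that the total beyond-ZPE vibrational free
energy Σ RT ln(1−e^{−hcν/k_BT}) equals a fixed baseline plus the record's
prescribed ΔG−ΔE+ZPE offset; `e_high` is then back-computed from the
actual ZPE and a random solvation/dispersion split so the ΔE+ZPE scale is
exact too. The absolute energy offset and the component split are seeded
nuisance structure — they stress sign and unit handling — and never move a
prescribed observable. TS records append one negative mode at the
prescribed imaginary wavenumber. Records deliberately omit geometries:
translation/rotation terms would be identical across records anyway, and
their omission keeps the free-energy inversion exact.

Presets encode the two published cluster-model profiles (barriers
9.3/10.9/11.8/12.2 with intermediates −8.8/−8.1 and reactant spin gaps
19.2/10.4/10.9; barriers 14.5/15.8/21.2/23.1 with the C1 TS imaginary
modes i1495/i1534) and the per-model free-energy barrier table. Imaginary
wavenumbers not individually published (model-B TSs, model-C C2 TSs) use
representative values above 1000 cm⁻¹, consistent with the reported ">i1000"
character; the model-C intermediate placement encodes only the ~9 kcal/mol
C2-below-C1 difference, not absolute values.

`gen_toy_pdb` writes fixed-width PDB text with residues on a 5 Å cubic
lattice — far enough apart that no accidental hydrogen-bond contacts or
field singularities arise — with backbone plus the side-chain atoms the
charge model needs. Residue order along the chain is seeded nuisance;
composition is exact by construction.

**What the generators do not emulate:** real electronic structure
(anharmonicity, mode coupling, solvation physics), conformational
flexibility, realistic protein geometry. Passing the recovery tests
demonstrates that the bookkeeping — assembly, projection, thermochemistry,
branching, censusing — is exact and unit-clean; it does not validate any
DFT energetics, which enter only as recorded inputs.

## Problem sizes

The test suite and acceptance script run synthetic systems of 2–5 atoms,
landscapes of ~10 records, 50-prescription recovery sweeps and toy
structures of ≤61 residues — sizes chosen because every check they support
is exact (recovery to 1e-9 kcal/mol, eigen-round-trips to 1e-6 cm⁻¹), so
larger fixtures would add cost without adding information.

## Known limitations

- No anharmonic corrections, hindered rotors, or variational TST; Wigner is
  the only tunnelling model (no Eckart/SCT).
- Electric-field response ignores field-dependent geometry relaxation and,
  by default, polarizability.
- The electrostatics module is formal-charge/vacuum-Coulomb; no pKa
  prediction, partial charges or continuum screening.
- Ingestion of vendor QC output files is delegated to adapters behind the
  record contract; the core parses only its own format, XYZ and PDB.
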