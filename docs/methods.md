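# Methods

## Cage construction

The C60-Ih geometry is generated from the canonical truncated-icosahedron
vertex orbit — the even (cyclic) permutations of the sign families
(0, ±1, ±3φ), (±1, ±(2+φ), ±2φ), (±2, ±(1+2φ), ±φ), φ the golden ratio —
and scaled so the mean nearest-neighbor distance equals the requested
edge length (default 1.44 Å, the experimental mean C–C bond of C60).
Atoms are renumbered by ascending (z, y, x) so edge and face indices are
reproducible across runs.  Bonds are pairs within 1.2× the minimum
interatomic distance; the next shell sits at ≥ 1.6×, so the cutoff is
insensitive.  Faces are perceived by geometric tracing: each vertex's
neighbors are ordered counterclockwise about the outward radial
direction and directed edges are walked until the orbit closes.  Graphs
without coordinates (test polyhedra) fall back to the combinatorial
rotation system of a planar embedding; both routes give identical faces
for C60.  The face set must satisfy V − E + F = 2 or an error is raised.

Automorphisms are counted by backtracking over vertices in BFS order:
every non-root vertex already has a mapped neighbor, so candidate images
come from intersecting the images' neighborhoods.  For the cage this
visits a few thousand nodes and returns 120.

## Bond-order variants

Orders are exact rationals (`fractions.Fraction`), so the per-atom
closure Σ incident orders = 4 holds identically, not within a tolerance.
Integer variants are found by a backtracking constraint solver over
edges in canonical order, trying smaller orders first — the first
solution is therefore the lexicographically smallest — with interval
pruning on each atom's remaining valence and optional per-pentagon
double-bond counts for the motif constraints:

- FB1 needs no search (6:6 ↦ 2, 6:5 ↦ 1 closes every atom exactly).
- FB2/FB3 fix the two distinguished pentagons (the canonical antipodal
  pair: the lowest-index pentagon and the pentagon at maximal graph
  distance from it) and require two internal doubles in each remaining
  pentagon.  A counting argument shows the FB2 completion is unique:
  the ten outward doubles of the special pentagons each saturate one
  vertex of one of the ten remaining pentagons, and a 4-path has a
  unique perfect matching.
- FB4 requires exactly one internal double per pentagon.

Kekulé structures are counted by matching the lowest-index unmatched
vertex first, memoizing on the matched-vertex bitmask; with the z-sorted
vertex order the frontier stays narrow and C60 finishes in ~20 ms
(12,500).  A subset-enumeration brute force cross-checks small graphs.

Formal charges: the default model is the bookkeeping identity
q_i = 4 − Σ incident orders, which is exactly zero for every shipped
variant.  Because the force field that motivated this comparison assigns
small nonzero charges by an undocumented internal scheme, an optional
transparent stand-in ("increment") is provided: each bond of order b
moves δ·(b−1) e from its lower- to its higher-index endpoint (δ default
0.01 e).  It is zero-sum by construction and gives the fixed-bond
variants nonzero dipoles to exercise the electrostatics machinery; it
makes no claim to reproduce any particular published dipole value.

## Energy function and units

Units: Å, fs, amu, kJ/mol, e; 1 amu·Å²/fs² = 1.0e4 kJ/mol,
k_e = 1389.35 kJ·mol⁻¹·Å·e⁻², k_B = 8.314462618e-3 kJ/mol/K.

- **Stretch** ½ k(b) (r0(b) − r)² per bond.  k and r0 interpolate
  linearly in the order b between k(1) = 1600, k(2) = 3200 kJ/mol/Å²
  and r0(1) = 1.455 Å, r0(2) = 1.391 Å.  The length anchors are the
  experimental 6:5 / 6:6 bond lengths of C60, chosen so relaxed
  structures reproduce the observed short/long separation; the
  stiffness anchors are plausible C–C values, so *absolute* frequencies
  are parameter-conditioned (see Limitations).
- **Planarity** ½ l_p R_p² per atom (l_p = 400 kJ/mol/Å²), R_p the
  distance from the atom to the plane of its three neighbors.  The
  gradient is analytic; the p1-vertex term is obtained from translation
  invariance (∂p1 = −∂a − ∂p2 − ∂p3), which also guarantees an exactly
  vanishing net force.
- **Born–Mayer vdW** A e^(−B r) − C r⁻⁶ with A = 3.0e5 kJ/mol,
  B = 3.6 Å⁻¹, C = 2.4e3 kJ/mol·Å⁶ (sign convention: repulsive
  exponential, attractive dispersion; the curve crosses zero near
  3.4 Å).  1-2 and 1-3 pairs are excluded; 1-4 and beyond are fully
  included.  The nearest included pairs are the hexagon para pairs at
  ~2.88 Å, on the repulsive wall: they lengthen all relaxed bonds by
  ~+0.01 Å and split the 6:6/6:5 environments even when all bond
  parameters are equal (see Limitations).
- **Coulomb** k_e q q / r over the same pair list, open boundary — for
  a single 60-atom molecule a direct sum is exact and an Ewald/periodic
  treatment would be a complication, not an improvement.  ESP maps use
  the same direct sum on a cubic grid (default 16 Å extent, 0.25 Å
  spacing, masked within 0.5 Å of nuclei), with ±50%-of-maximum
  iso-level extraction.

All gradients are analytic and verified against central finite
differences to ≤ 1e-5 relative on dozens of jittered configurations.

## Minimization

Three phases: (1) steepest descent with a backtracking line search
capped at 0.01 Å displacement per atom; (2) annealing — velocity-Verlet
dynamics (dt 0.5 fs) with velocities damped by 0.9 whenever the power
F·v is negative, convergence tested every 200 steps (window energy drop
< 0.05 kJ/mol); (3) an optional L-BFGS polish using the analytic
gradient, restarted until the gradient 2-norm falls below the requested
tolerance (default 1e-4 kJ/mol/Å).  The polish exists because phases
1–2, run alone, approach stationarity only linearly and would need
~10⁵ evaluations to certify |∇E| < 1e-4; L-BFGS reaches it in a few
hundred.  All three phases descend the same surface, so the minimizer
found is the same basin in every case tested.

## Dynamics

Velocity Verlet; NVE or Berendsen weak coupling
λ = √(1 + (dt/τ)(T0/T − 1)).  λ is clamped to [0.5, 2] per step —
far-from-target starts (e.g. zero velocities) would otherwise amplify
floating-point noise geometrically.  The center-of-mass momentum is
subtracted every step (internal forces leak ~1e-13 net force through
round-off, and thermostat rescaling amplifies it), keeping COM drift
below 1e-6 Å over any run.  Initial velocities are Maxwell–Boltzmann at
the target temperature, with rigid-body linear and angular momentum
projected out and the kinetic temperature rescaled to exactly T0
(DOF = 3N − 6).  Defaults: dt 1 fs, 298 K, τ 100 fs, record stride 10.

Production length is 100 ps (not the nanosecond scale a survey-grade
study would use): the Rg spectrum then has 0.01 THz raw resolution,
ample for THz-scale cage modes, and one variant runs in under a minute
on one CPU.  NVE drift at dt 0.5 fs is < 0.1% of the kinetic energy
over 10 ps and scales down roughly quadratically with dt.

## Spectral analysis

`power_spectrum` returns the one-sided, mean-subtracted periodogram
normalized so the powers sum to the signal variance; the fundamental
frequency is the non-DC power argmax (ties to lower frequency).  An
optional Welch mode averages K non-overlapping segment periodograms
(pipeline default K = 8), trading resolution (0.08 THz at 100 ps/10 fs)
for a 1/K variance reduction — on a single-shot thermal recording the
raw periodogram has ~100% per-bin noise and local-maximum counting is
meaningless.

Distinct modes are identified by `spectral_bands`: candidate peaks must
exceed 5× the median power (the chi-square noise floor — pure-noise
signals produce no candidates in 100/100 seeded trials) *and* have
prominence ≥ 30% of the spectrum maximum (sub-maxima riding on one band
are not modes), and surviving candidates within 0.5 THz — the scale
separating distinct cage modes — merge into one band.  These thresholds
were calibrated on synthetic signals with known tone content, not on
the MD output.

## Shannon entropy

Computed on the 90 bond lengths of the minimized structure by default
(an option pools all trajectory frames instead), using a fixed bin grid
anchored at 1.30 Å with 0.01 Å width (extended on the same grid if data
fall outside [1.30, 1.55] Å, so no mass is dropped) and base-2 logs over
nonempty bins.  Values sitting exactly on a bin edge are assigned to the
upper bin with a 1e-6-bin guard against round-off.  Two equally abundant
groups in two bins give exactly 1 bit; C60's 30/60 class split gives
log₂3 − 2/3·1 ≈ 0.918 bits.

## What the synthetic generators emulate

- `jittered_cage`: isotropic Gaussian thermal displacement (default
  σ = 0.05 Å, the RMS amplitude scale of a stiff covalent cage near
  room temperature).  It has no mode structure or bond-length
  correlations, so it validates energies/gradients, not thermodynamics.
- `synthetic_rg_signal`: baseline 3.44 Å (the cage's Rg) plus seeded
  sinusoids and white Gaussian noise — a stand-in for Rg recordings
  with *known* frequency content.  It has no 1/f drift, no anharmonic
  satellites and no chi-square band noise, so a green tone-recovery
  test establishes estimator correctness, not MD realism.
- `random_zero_sum_charges`: i.i.d. Gaussian charges recentered to an
  exactly zero sum, for exercising dipole/ESP code with nonzero inputs.

## Design choices on genuinely open points

- The two distinguished pentagons of FB2/FB3 are chosen by graph
  distance (canonical antipodal pair); remaining freedom is resolved
  lexicographically.  The published motif drawings do not pin down a
  global double-bond map, so these structures are *a* faithful
  realization, not provably *the* one — FB2's completion happens to be
  forced, FB4's is not.
- Rectangular window by default for spectra (peak location, not
  amplitude fidelity, is the target); Hann available.
- The pipeline's default charge model is the exact formal model (all
  zeros ⇒ all dipoles exactly zero); the increment model is opt-in.
- Entropy defaults to minimized-structure lengths; trajectory pooling
  is available (`entropy_source: trajectory`).

## Known limitations

- **Absolute frequencies are parameter-conditioned.**  With k linear in
  bond order and total order fixed at 120, Σ k_b is *identical* across
  variants, so inter-variant fundamental-frequency differences come
  only from second-order effects (bond-length weighting, mode mixing,
  anharmonicity) and span ≲ 0.1 THz here — an order of magnitude less
  than a force field whose stiffness is not constrained to interpolate
  linearly.  A 100 ps thermal estimate of the spectral argmax wanders
  by more than that within a band, so entropy–frequency rank statements
  across the fixed-bond variants are at the edge of resolvability at
  this scale; the harmonic (Hessian-free ground truth via normal-mode
  frequencies is reported in the analysis notes) ordering is inverse to
  the entropy ordering, but the finite-time estimator does not resolve
  it reliably.
- **The 1-4 vdW inclusion shifts and splits bond lengths.**  Hexagon
  para pairs at 2.88 Å push relaxed bonds ~0.01 Å past their r0 and
  split the resonance variant's 6:6/6:5 environments by ~0.011 Å —
  comparable to the entropy bin width, so the resonance variant
  occupies two bins rather than one.
- Entropy comparisons between fixed-bond variants are sensitive to the
  global double-bond placement: low-symmetry realizations have many
  inequivalent bond environments and systematically higher entropy than
  symmetric drawings with the same motif counts.
- No angle-bending or torsion terms, no solvent, no periodic boundary,
  no quantum corrections; heats of formation are out of scope.
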