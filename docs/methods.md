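# Methods

## Model and scope

`cagefield` treats a solvated host–guest catalyst as a *labeled
point-charge ensemble*: each atom carries a position (Å), a fixed partial
charge (e) and a group label (oxidant periphery, cage, solvent, substrate,
…). Everything the package computes — fields, dipoles, stabilization
energies, populations, free-energy profiles — is a function of that
ensemble plus a handful of printed scalars (reaction barriers,
temperature). Electronic structure is out of scope by design: barriers
are consumed as inputs, fields are bare Coulomb sums (no polarisation, no
periodic imaging, no QM charge densities), and no dynamics are propagated.

## Reaction-axis frame

All reported field and dipole components live in a per-frame orthonormal
frame: **z** along Fe→O (the reaction axis), **y** the lateral
selectivity axis, **x = y × z**. Two conventions are genuinely open and
are therefore explicit, configurable parameters, echoed in every report:

- **Lateral reference.** Nothing intrinsic to Fe=O fixes the y
  direction. We define y as the component of (centroid of a user-named
  `lateral_ref` selection − origin) orthogonal to z. The synthetic system
  defaults to the substrate ring centroid. Sign conventions of F_y and
  μ_y are only reproducible if the lateral reference is recorded, which
  is why `RunConfig` serialises it.
- **Origin / probe point.** The field can be probed at the Fe site, the
  O site, the Fe–O midpoint, or the three-point average; published
  field-on-bond tools differ here and the choice moves magnitudes by a
  few percent. Default: midpoint, with `average3` available. The axis
  origin defaults to the same midpoint so that probe and frame agree.

Degenerate inputs are errors, not warnings: |O−Fe| < 0.5 Å, a lateral
centroid within 1e-6 of collinearity, or a source charge within 1e-6 Å of
the probe all raise typed exceptions.

## Units and constants

Positions Å, charges e, fields V Å⁻¹, dipoles Debye, energies kcal mol⁻¹,
temperature K. Three constants do the unit work and are deliberately kept
distinct (they agree only to ~3 significant figures, and conflating them
is a classic bug): k_C = 14.3996 V·Å·e⁻¹ (Coulomb field),
k_D = 4.80320 D per e·Å (dipole), k_E = 4.8009 kcal mol⁻¹ D⁻¹ (V/Å)⁻¹
(field–dipole energy). R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹.

## Field–dipole energetics and sign convention

Per axis, ΔE_a = k_E · F_a · μ_a; with full vectors,
ΔE = k_E |F||μ| cos θ. Components follow the Gaussian electronic-structure
program's convention for field and dipole directions, under which a
negative ΔE is stabilizing. This plus-sign component form is the only
convention consistent with all five mutually consistent cells of the
reference stabilization table (reactant −12.07, pro-R TS −17.95, pro-S TS
−9.66 kcal/mol along z; +1.61 and +1.84 along y). The sixth published
cell, −0.32 kcal/mol for the pro-R TS lateral term, is *inconsistent with
its own printed components* (0.20 V/Å × −0.40 D × k_E = −0.38); it was
plausibly computed through the full-vector cosine form with an unprinted
x-component. `table1_report` flags charged-group dipoles (origin
dependent) and the package neither asserts nor reproduces that cell.

Dipoles of neutral groups are origin-independent (verified to 1e-10 D
under 5 Å translations); charged groups carry an explicit origin
(geometric center by default, configurable) and a mandatory warning flag.

## Selectivity statistics

- **Populations.** The empirical normalised histogram of an unbiased
  equilibrium distance series is reported as the Boltzmann population —
  the two coincide under equilibrium sampling, so no reweighting is
  applied. Bin width defaults to 0.1 Å; the mode tie-break goes to the
  smaller distance (the closer-approach, chemically relevant bin), and
  the representative snapshot is the *earliest* frame in the mode bin.
- **Contact occupancy** uses a strict `<` cutoff (a frame at exactly the
  cutoff is not a contact); distance-shell *selections*, by contrast, use
  a closed `≤` boundary. Both boundaries are documented at the API.
- **Ratios.** r = exp(ΔΔE‡/RT) with the major product labeled by the
  lower barrier; percent_major = 100·r/(1+r) is numerically identical to
  the two-state Boltzmann fraction, and the spin-state preference uses
  the same closed form. With the published barrier pair
  (4.8, 7.81) kcal/mol at 298.15 K the computed ratio is 160.8 : 1;
  the reference prints 159 : 1, consistent within the ±0.005 rounding of
  the printed barriers.

## Jarzynski / staged-pulling PMF

ΔG = −β⁻¹ ln ⟨e^(−βW)⟩ is evaluated in log-sum-exp form, so works of any
magnitude are safe. Staged (adaptive) pulling is stitched **stagewise**:
the published adaptive protocol restarts each stage's ensemble from the
configuration nearest the stage average, which at the work level means
each stage's increments are re-zeroed at the stage boundary and averaged
independently; cumulative summation anchored at 0 gives the profile. The
trajectory-selection criterion of the original adaptive scheme is not
otherwise modeled; a full-trace (non-adaptive) estimator is provided for
comparison. Uncertainty is a percentile bootstrap over whole trajectories
(not BCa — simpler and adequate at the ensemble sizes used here);
intervals are clipped to contain the point estimate.

Estimator properties asserted in tests: Jensen bound ΔG ≤ ⟨W⟩, exact
noiseless recovery, invariance under trajectory permutation, exact
covariance under constant work shifts.

## Synthetic generator: what it emulates, what it does not

The generator exists so that every downstream computation has a ground
truth recomputable from the spec alone:

- **Cage system** (`gen_cage_system`): Fe=O (1.65 Å) centered at the
  origin; four +1 e peripheral sites on an 8 Å ring in the z = 0 plane
  (symmetric, so their field cancels analytically at the center); 24
  neutral ±0.2 e polar pairs on a 12 Å shell; 30 neutral ±0.1 e solvent
  pairs in a 14–16 Å shell; a neutral substrate 6-ring at (0, 4, 0) Å
  fixing the y-axis; far counter-ions neutralising the system (placed at
  4× the solvent radius so near-field analytics stay simple). Sites
  closer than 0.8 Å are re-drawn, with an error after 100 attempts.
  Frame 0 is jitter-free and reproduces the recorded ground-truth field
  and group dipoles exactly; frames t ≥ 1 add isotropic N(0, 0.1 Å)
  displacements, uncorrelated across frames — the simplest model that
  makes field series fluctuate, sufficient because downstream statistics
  need only stationarity.
- **Distance series**: pro-R from a p·N(2.6, 0.2²) + (1−p)·N(3.4, 0.2²)
  mixture with p = 0.7, pro-S with mirrored weights — a two-population
  near/far structure with closed-form means.
- **Contact series**: Bernoulli(0.88) choice between truncated normals
  centered 3.8 Å (below the 5 Å cutoff) and 6.5 Å (above), truncation
  width a quarter of the distance to the cutoff.
- **Work traces**: per-stage Gaussian increments with mean
  ΔPMF + βσ²/2 and variance σ². The dissipation offset makes the
  Jarzynski average recover the input profile *exactly in expectation*
  (Gaussian closed form ΔG = ⟨W⟩ − βσ²/2), giving an exact rather than
  approximate recovery target. Default layout mirrors the study
  protocol: 3→23 Å in 10 stages.

What the generator does **not** emulate: real force-field energetics,
correlated dynamics, periodic solvent boxes, chemically valid cage
topology, or anharmonic work distributions. Passing tests therefore
demonstrate correctness of the *analysis machinery* (estimators,
projections, conventions, statistics) under the stated models — not that
any particular real cage exhibits particular field magnitudes or
occupancies. The trajectory-averaged field components, the 88% stacking
occupancy on the real system and the barriers themselves come from
MD/QM/MM and enter only as printed inputs.

## Problem sizes and numerical choices

Stochastic recovery checks use n = 10⁵ samples for series statistics
(binomial/mixture standard errors ≪ tolerances) and 10³ trajectories per
stage with σ = 1 kcal/mol for the stitched-PMF check; bootstrap bands use
100–500 resamples. All generators and bootstraps take explicit integer
seeds and are bit-reproducible. Superposition residuals are held to
1e-10 V/Å, axis-frame orthonormality to 1e-10, neutral-dipole translation
invariance to 1e-10 D; histogram normalisation to 1e-9. Selection
resolution sorts indices, so results are order-independent; the
`most_populated_frame` tie rule (earliest frame) makes the representative
snapshot deterministic.

## Known limitations

- Non-periodic electrostatics only; fields across a periodic solvent box
  would need minimum-image or Ewald treatment.
- Fixed point charges: no polarisation response, no higher multipoles in
  the stabilization expansion (quadrupole terms omitted).
- The stagewise stitcher assumes at least two trajectories per stage and
  equal stage membership across trajectories (long-form CSV must be
  rectangular).
- Percentile bootstrap undercovers slightly for strongly skewed
  exponential averages (large βσ); the second-order cumulant estimator is
  deliberately not included in v1.
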