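# Methods

## Model and conventions

**Reduced measurement model.** A 3×3 Mueller polarimeter with `a` analyzer
and `g` generator states measures `P = A M G`, with `A` (a×3) holding the
first three Stokes analysis coefficients of each analyzer state, `G` (3×g)
the first three Stokes components of each generated state, and `M` the
top-left 3×3 block of the sample's Mueller matrix. Circular components
(the fourth Stokes row/column) are invisible to such an instrument and are
outside the model. The air measurement is `P_air = A G`.

**Sample family.** All calibration samples are dichroic retarders (DR):
attenuations `q ≥ r` along orthogonal principal axes plus retardance `Δ`.
The reduced matrix is `R(−2θ) · core(q, r, Δ) · R(2θ)` with
`core = [[q+r, q−r, 0], [q−r, q+r, 0], [0, 0, 2qr·cosΔ]]` and `R` the
rotation on the (s0, s1, s2) subspace. Its eigenvalues are the
θ-independent triple `(2q, 2r, 2qr·cosΔ)`. A linear polarizer is the
`Δ = 0` limit; a wave plate the `q ≈ r` limit.

**Angle convention.** All orientations are physical mount angles in
degrees. The azimuth doubles inside the rotation, and the sense is fixed
so an ideal polarizer at +45° produces/analyzes the Stokes state
`(1, 0, 1)` — i.e. `s2 = I(45°) − I(135°)`. One consequence used
throughout: a linear element's matrix has period 180° in θ, so orientation
searches run over `[0°, 180°)`.

**Scale conventions.** The DR core carries no ½ radiometric prefactor
(ideal LP eigenvalues are (2, 0, 0)); analyzer rows carry the ½ of the
intensity-splitting detector model. Neither matters to the calibration:
`A` and `G` are recoverable only up to one reciprocal gain pair
`(sG, A/s)`, which cancels in every Mueller estimate `A⁺ P G⁺`. The
design-stage sample models are normalized to unit transmission
(`q + r = 1`): ideal LP (1, 0), QWP (½, ½, Δ = 90°), finite-extinction LP
`(ER/(ER+1), 1/(ER+1))`. This relative LP:QWP scaling is what the
published optimal-design values correspond to.

## Calibration algorithm

1. **Intermediate matrices.** `D_i = P_air⁺ P_i` is similar to `M_i`
   (`G D_i = M_i G`). The pseudoinverse is *truncated to rank 3*: the
   reduced model makes `P_air` exactly rank 3, and inverting the
   noise-dominated trailing singular value of a four-state air matrix
   would flood `D` with O(1) spurious eigenvalues. This truncation is the
   single most important numerical safeguard in the pipeline.
2. **Eigenvalue assignment.** For `g > 3`, `D` carries one spurious
   rank-deficiency eigenvalue (≈0) besides the sample triple. The genuine
   triple is selected by a type-aware rule: for LPs, the triple most
   consistent with the zero-retardance identity `λ₃ = λ₁λ₂/2`; for wave
   plates, the two largest eigenvalues are `(2q, 2r)` and the `λ₃`
   candidate *farthest* from zero survives (an imperfect QWP has a small
   but genuine `λ₃` that must not be confused with the spurious zero).
   Noise can split near-degenerate pairs into complex conjugates; real
   parts are used, with imaginary parts above 10 % of the spectral radius
   treated as a data inconsistency.
3. **Orientation fitting.** Each sample matrix is rebuilt from its
   measured eigenvalues at a trial orientation; `K(θ) = Σ HᵢᵀHᵢ` with
   `Hᵢ = Dᵢᵀ⊗I₃ − I_g⊗Mᵢ` (column-stacking vec; the transpose on `D` is
   required for `H vec(G) = vec(GD − MG)` to hold). Free orientations
   minimize μ₁/μ₂ of K by an exhaustive joint grid (2° per angle up to two
   free angles, 6° for three) plus Nelder–Mead, then a joint Gauss–Newton
   pass on the stacked residuals `Hᵢ(θ)·vec(G)` over (θ, vec G) with a
   unit-norm gauge row. The last step matters: the μ₁/μ₂ landscape is
   quadratic around the optimum and bottoms out in eigensolver noise at
   ~10⁻⁶ degree, whereas the joint least-squares residual is exactly zero
   at the noiseless solution, so Gauss–Newton converges to machine
   precision (noiseless recovery ~10⁻¹⁵ relative, versus ~10⁻⁸ without).
4. **Null-space solve.** `vec(G)` is the eigenvector of K's smallest
   eigenvalue (symmetric eigensolver; K is a Gram-matrix sum), un-stacked
   column-wise, unit Frobenius norm, sign fixed by a positive first-row
   sum. `A = P_air G⁺` then solves the air equation in least squares.

### Identifiability safeguards

Two genuine degeneracies of linear-subspace calibration required design
decisions beyond the basic algorithm:

* **Spurious exact solutions.** When sample models are rank-deficient
  (ideal LP: rank 1; ideal QWP: rank 2) and the air matrix is wider than
  3×3, rank-one matrices `u wᵀ` (with `w` the common left-null vector of
  all `D_i` and `u` a common null vector of the trial `Mᵢ`) satisfy every
  Sylvester equation exactly whenever the trial angles take two or fewer
  distinct values. The fitter therefore rejects candidate minima whose K
  null vector un-stacks to a near-rank-deficient G (singular-value ratio
  below 0.02).
* **Reflection ambiguity.** The measurements determine the orientations
  only up to the global reflection θᵢ → −θᵢ (with the 0° reference fixed),
  under which `G → diag(1, 1, −1) G`: both branches reproduce every
  intensity matrix exactly. This is intrinsic — linear-only states carry
  no handedness. The resolution mirrors bench practice: a sample's
  orientation is always known roughly (it was placed by hand), so
  `CalibrationSample.theta_hint` (accuracy of tens of degrees suffices;
  default search window ±20°) selects the physical branch and
  incidentally shrinks the search grid. Without hints the fitter searches
  the full period and returns an arbitrary branch.

A calibration set is flagged degenerate — `DegenerateCalibrationWarning`,
`CalibrationResult.degenerate` — when μ₁/μ₂ exceeds 0.1, when μ₂/μ_max
falls below 10⁻⁶ (μ₂ itself numerically null, as for the two-sample
sets), or when the recovered G is rank-deficient.

## Optimal design (SSLE-R search)

For a candidate sample set at trial orientations the conditioning merit is
the SSLE-R, `μ₂/μ_max` of K built from the ideal sample models through a
nominal instrument (`D = (AG)⁺ A M G`; the result is independent of which
full-rank instrument is used, and three- and four-state instruments give
identical values). Landscapes are evaluated on dense grids (1° for ≤2 free
angles, 2° for 3) with per-sample K-term caching and batched
eigendecomposition, all grid maxima within 10⁻⁴ relative are reported
(the landscapes have many symmetric optima), and the best point is polished
by Nelder–Mead.

Computed maxima, against the published table:

* Confs. 3–9 agree to ~1 % (e.g. LP+2×QWP: 0.1215 vs 0.1198 at
  (18.6°, 161.4°) vs the published (19°, 162°); 2×LP+QWP: 0.0593 with the
  published (90°, 117°) among the equivalent maxima).
* The four-LP set computes 0.2608 at exactly (45°, 90°, 135°) vs the
  published 0.2474 — about 5 % high under every modeling variant tried;
  the published cross-configuration *ordering* (the design conclusion) is
  reproduced exactly.
* The two-sample sets (LP+LP, LP+QWP at ER 100:1) compute μ₂/μ_max ≈
  6×10⁻⁹ and 5×10⁻⁹: with `q + r = 1` the gap between `λ₂ = 2r` and
  `λ₃ = 2qr` is `2r(1−q) ≈ 2×10⁻⁴` and μ₂ scales with its square. The
  published values (5.9×10⁻⁵, 5.0×10⁻⁵) match in mantissa and ratio but
  not magnitude; no zero-retardance ER-100 polarizer model can reach them.
  Either way the operative conclusion is identical: these sets leave G
  numerically undetermined and must not be used.

## Noise study

Each replicate simulates the air and sample measurements of a
configuration with a four-state instrument (truth samples = the
configuration's design models at the optimal orientations, truth
orientations passed as hints), adds independent Gaussian noise of standard
deviation `0.005·‖P‖_F` to every element of every intensity matrix, runs
the full calibration, and records
`ε_X = ‖s·X_cal − X_true‖_F / N_X` with `s` the least-squares matching
scalar and `N_X` the element count. Default 100 replicates, seeds =
base + replicate index; degenerate or failed replicates are flagged, never
dropped. At 0.5 % noise the four-sample sets calibrate to
`ε_G ≈ 3–4×10⁻³` (median), the three-sample sets to `4–5×10⁻³`, ordered
inversely to their SSLE-R; the two-sample sets produce essentially random
G within their double null space (`ε_G ≈ 0.2`). The published mean errors
for the two-sample sets (0.097 and 0.870) are not reproduced: under the
scale-matched definition the error is bounded by `‖G‖/N ≈ 0.24`, so 0.870
is unreachable, and both sets are equally degenerate here so their errors
come out nearly equal rather than 9× apart.

## Imaging

`reconstruct_mueller` applies the two fixed pseudoinverses per pixel
(`a, g ≤ 4`, exact least squares). Mueller images are m00-normalized
before residuals and anisotropy, since absolute gain is not calibratable.
The residual metric is `‖M_est − M_ref‖_F / 9` on normalized matrices. The
anisotropy parameter, from the Mueller-matrix-transformation family of
tissue metrics (not part of the calibration itself), uses
`b = (m₁₁ + m₂₂)/2`, `t = ½√((m₁₁−m₂₂)² + (m₁₂+m₂₁)²)` (0-based indices)
and `Aniso = 2|b|t/(b² + t²)` ∈ [0, 1]: rotation-invariant, 0 for the
identity. The rotating-polarizer validation simulates a high-contrast LP
swept 0°–350° in 10° steps through a perturbed truth instrument;
reconstruction through the calibrated matrices beats reconstruction
through the nominal ones at every tested noise level (0–1 %), noiselessly
by ~7 orders of magnitude.

## What the synthetic data do and do not show

The simulator reproduces the error sources the method is designed for —
orientation offsets, attenuation spread, residual source polarization,
additive Gaussian radiometric noise — under exact linearity. It does not
model shot noise, detector nonlinearity, spectral dependence, beam
wander, or polarization artifacts of imaging optics; passing tests
demonstrate algorithmic correctness and noise robustness under the stated
model, not end-to-end hardware performance.

## Problem sizes and runtimes

Orientation-search grids: 1° for one/two free angles (180/32 400 points),
2° for three (729 000 points), batched eigendecomposition ~40 s for the
full nine-configuration table on one CPU. Monte-Carlo studies: 100
replicates per configuration (~0.05 s per replicate for four-sample
sets). The test suite runs the full acceptance layer in a few minutes.
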