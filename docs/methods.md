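# Methods

## Setting

`pacemap` solves a patient-specific localization problem: given a set of
endocardial pacing sites with known catheter coordinates (mm, a
patient-local Cartesian frame — no anatomical registration is attempted)
and the 12-lead ECG each produces, estimate the position of a further
site from its ECG alone.  The package works in *emulation* mode
throughout: the "unknown" target is itself a pacing site whose true
position is hidden from the localizer but used to score predictions and
to emulate the operator's distance judgements in the iterative protocol.
Traces record this explicitly; no claim of closed-loop clinical use is
implied.

## Signal preprocessing

Each site's beats are averaged sample-wise into a representative beat
(inputs are assumed pre-aligned within a site; no cross-correlation
realignment is applied, and no filtering or baseline-wander removal —
preprocessed input is assumed).  The **composite signal** is the
per-sample sum of absolute voltages over the 12 leads; the sum of
magnitudes gives one robust alignment point without sign cancellation
between leads of opposite polarity.  Argmax ties break to the earliest
sample.  The **splice vector** concatenates, in canonical lead order
(I, II, III, aVR, aVL, aVF, V1–V6), the 150-ms per-lead windows centered
on the composite maximum (center at offset ⌊W/2⌋ for window length W; a
window that would overrun the recording raises an error rather than
padding).  At the default 1 kHz this gives a 12 × 150 = 1800-element
vector; real data are used at their native rate with W recomputed, never
resampled.

**QRS onset** is automated (manual extraction is not reproducible): scan
backward from the composite argmax and return the first sample of the
contiguous run exceeding 5% of the composite maximum.  The 5% threshold
is a conventional small fraction; on the wavefront simulator the detected
onset lands within ~6 ms of the true earliest activation.  **QRS
integrals** are signed trapezoidal integrals of leads III, V2, V6 over
[onset, onset + 120 ms] inclusive (121 samples at 1 kHz, so a constant
1 mV lead integrates to exactly 120 mV·ms).  Signed — not rectified —
because the regression model needs linear predictors of position.

## Models

| model | information used | fit | prediction |
|-------|------------------|-----|------------|
| QIM | 3-lead QRS integrals | OLS, each coordinate on [1, I₁, I₂, I₃]; ≥ 5 sites | direct evaluation |
| DEM | 12-lead E12 distance | through-origin slope k₁ on all C(m,2) site pairs | multilateration |
| DCM | 12-lead correlation | through-origin slope k₂ on 1 − Corr | multilateration |
| DDM | 12-lead waveform differences | transfer matrix θ by least squares | averaged spatial offsets |

Conventions shared by DEM/DCM: the slope is k = Σ d·m / Σ m² (the
closed-form through-origin least squares; only the intercept is
constrained, k is not sign-constrained, though it is positive on any
non-degenerate training set); estimated distances are clamped at 0
before multilateration.  A lead that is constant in either input has no
defined Pearson correlation and is dropped from the 12-lead average
(divisor reduced); an all-degenerate pair raises an error.  E12's inner
normalization is 1/N inside the per-lead root, N the window length in
samples, making E12 a sum of scaled per-lead Euclidean norms — hence a
true metric.

**Multilateration.**  J(x) = Σ(‖x − aᵢ‖ − d̂ᵢ)² is nonconvex: three
coplanar anchors have two mirror minima, and inconsistent distances can
create spurious local minima.  The solver is multi-start: a
distance-weighted centroid of the anchors (weights 1/(d̂ᵢ + ε)) plus one
start per anchor, each nudged 10⁻⁶·scale toward the centroid because the
residual is not differentiable exactly at an anchor; each start is
polished with a Levenberg–Marquardt least-squares iteration on the
residuals and the lowest-J result is returned.  The trust-region
least-squares polish (rather than a simplex search) is what reliably
reaches the 10⁻⁶ mm regime on exact-distance instances; the multi-start
set is the defense against the nonconvexity.  At least 3 anchors are
required.

**DDM.**  With m modeling sites the difference basis holds all C(m,2)
ordered pairs (i < j) — the generalization of the 3-site construction
that privileges no reference site.  This basis is structurally rank
deficient (W_jk = W_ik − W_ij), so the transfer matrix is the SVD
minimum-norm least-squares solution; a diagnostics flag records the
deficiency, and a small relative ridge (10⁻⁸) exists only as a fallback
if the SVD fails to converge.  The prediction averages Pᵢ + ΔP̂*ᵢ
uniformly over modeling sites (the natural weighting for m > 3, where
none is distinguished).  Two exact identities, both tested: if the
waveform map is affine and the target lies in the modeling sites' affine
span, recovery is exact to machine precision; if the target lies outside
the span, the prediction is the orthogonal projection of the target onto
the modeling plane (least squares through a scaled-isometry forward map
reduces to least squares in position space).

## Protocol emulation

Selection schemes: *hitrate* — a target needs ≥ 5 neighbors at distance
strictly in (15, 35) mm; *range* — ≥ 5 neighbors at ≤ 35 mm (printed
comparatives followed literally: 15 and 35 excluded in the strict band,
35 included in the range scheme).  The qualifying neighbors are exactly
the target's potential modeling set.

The loop: (1) initialize with the 3 farthest potential sites from the
target — 5 for QIM, whose 4-column design needs ≥ 5 rows; (2) fit and
predict; (3) terminate on a hit (error ≤ 15 mm, inclusive) or on
exhaustion — the hit check runs first, so a final-round prediction
within 15 mm counts as a hit rather than an exhaustion; (4) a prediction
more than 35 mm from the target is not credible → step 6; (5) otherwise
add the unused site nearest the prediction if within 15 mm of it
(inclusive); (6) fallback: add the unused site farthest from the
geometric center of the current modeling set.  "Farthest"/"nearest" ties
break lexicographically by site id, for determinism.  The *fixed*
variant replaces 4–6 with "add the unused site farthest from the
target", making the site sequence pure geometry, identical across
models.  Every round consumes at least one unused site or terminates, so
the loop ends within |potential| rounds.

**Outcomes.**  Hit = terminated by the 15-mm rule.  An exhausted trace is
an *early termination* if its final round still improved the estimated
error (the search was interrupted while converging), else a *miss*.
This is an operational reading of a qualitative clinical notion
("improvement interrupted by lack of sites") and is flagged as an
interpretation in emitted reports.  Error curves apply hold-at-minimum:
each trace contributes its running-minimum error, extended at its
overall minimum beyond its own length.  Reduced distance (minimum
modeling-site distance minus estimated error; positive = the search
region shrank) excludes rounds strictly after the first round attaining
the trace's minimum error; the minimum round itself counts.  The range
table reports mean/std ("Std", ddof = 1)/median ("Mid") of the initial
radius (maximum potential-site distance), the final minimum error, and
the modeling sites used, with two-sided *paired* t-tests between models
— paired because every model runs the identical target set; identical
samples are reported as p = 1 rather than NaN.  Raw p-values, no
multiple-testing correction.

## Synthetic data generator

The generator emulates the structure of a clinical multi-site pacing
study: by default 25 sites (clinical mean 25 ± 6) with 28 beats each
(mean 28 ± 8), positions sampled on an ellipsoid shell (semi-axes
30 × 35 × 50 mm — a ventricular-scale closed-form surface, not a heart
mesh) with ≥ 10 mm pairwise spacing by rejection.  Two forward modes:

**Affine mode** is a calibration standard, not a physiological model:
voltages(p) = b + A·p with fixed constants chosen so every model's core
assumption holds *exactly*:

- The common bump b (sin², support 160–240 ms, per-lead amplitudes
  1.1–2.0 mV, aVR inverted) dominates the composite signal, pinning the
  composite argmax (sample 200) and the detected onset (sample 166) for
  every position on the shell — so splice windows and integration
  windows never shift with position, keeping the full splice map
  globally affine.
- The position part uses three orthonormal temporal shapes (disjoint
  half-sine bumps inside the splice window, zero around the composite
  peak), mixed per lead by fixed orthogonal matrices, with gain
  0.02 mV/mm.  Each lead's 3-column block is a scaled isometry, so E12
  between any two sites is exactly proportional to their distance (DEM's
  assumption, and DDM's projection identity).
- Leads III, V2, V6 get the orthogonal mixings that map the common
  integral direction onto x, y, z respectively, making the
  integral-to-position map a perfectly conditioned scaled identity
  (QIM's assumption).

**Isotropic mode** is a traveling-wavefront dipole model: 256
quasi-uniform surface patches (Fibonacci lattice on the ellipsoid)
activate at t = 80 ms + distance/velocity with the stated conduction
velocity 0.7 m/s (70 mm → 100 ms); each contributes a Gaussian pulse
(σ = 8 ms) oriented along the local propagation direction, projected
onto 12 fixed unit lead vectors (textbook frontal-plane limb axes and
horizontal-plane precordial axes, hard-coded).  Contributions are
weighted 1/(1 + (d/30 mm)²): near-field sources dominate the early QRS,
which keeps the detectable onset within ~6 ms of the true activation
start (an unweighted sum rises with the activated area, ∝ t², and the
detected onset lags by 15+ ms).  Euclidean distance stands in for
geodesic propagation.  This mode is nonlinear in position and exercises
the models off their assumptions.

Beat noise is i.i.d. Gaussian per sample (default SD 0.05 mV, a
realistic post-filter ECG noise floor), drawn as sd × a standard-normal
stream that depends on the seed but not on sd — datasets differing only
in noise level share one underlying realization, scaled, which makes
noise-sensitivity comparisons paired.  A fixed config (including seed)
reproduces a dataset bit for bit.

What the generator does **not** emulate: torso volume conduction and
electrode geometry, anisotropic/heterogeneous conduction, repolarization
(T waves), baseline wander, powerline artifacts, beat-to-beat alignment
jitter, pacing artifacts, and the irregular site distributions of real
mapping studies.  Passing tests therefore demonstrate algorithmic
correctness and the models' behavior under controlled violations of
their assumptions — not clinical accuracy on real recordings.

## Numerical and design notes

- Degenerate least-squares systems anywhere (QIM design, DDM basis) take
  the SVD minimum-norm solution with a diagnostics flag; clinical site
  sets are frequently near-collinear.
- 1 − Corr is locally **quadratic** in inter-site distance for any
  smooth forward map (the first-order Pearson terms cancel), so DCM's
  proportionality calibration is exact only where the distortion
  cancels — e.g. symmetric anchor arrangements around the target, where
  DCM recovers to ≈ 0.2 mm; at generic 6-site geometry its bias is
  ~10 mm on the affine model.  This is a property of the correlation
  metric, consistent with DCM trailing the other models in evaluation,
  and it is why exactness checks for DCM use symmetric anchor clouds.
- Noise-sensitivity experiments use one target per seeded replicate with
  all remaining 24 sites as the modeling set (the localizer's
  full-information regime) over 50 replicates and noise SDs
  {0, 0.01, 0.05, 0.2} mV.
- Problem sizes throughout tests and the acceptance script — 6–25 sites
  per patient, 3 pooled patients, 20–100 random instances per oracle
  comparison — are desk-scale choices that keep every property
  observable in seconds to minutes.
- Dataset files: HDF5, one group per site, datasets written with
  timestamps disabled and sites in sorted order, so identical datasets
  produce identical bytes.  The MAT adapter is best-effort (repository
  layouts vary by lab) with overridable field names.

## Known limitations

- The early-termination rule and the reduced-distance exclusion rule are
  operational interpretations of one-sentence clinical definitions.
- QIM uses a global (composite-signal) onset, not per-lead onsets.
- The protocol's credibility checks use the target's true position, as
  the emulation setting requires; a clinical deployment would substitute
  the operator's map-based judgement.
- Multilateration guarantees a local minimum from the multi-start set,
  not the global minimum of J for arbitrary inconsistent distances.
- Lead vectors and dipole gains are reproducibility-oriented constants,
  not fitted to any torso model.
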