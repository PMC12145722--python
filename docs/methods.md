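# Methods

This note documents the models, numerical choices and limitations of the
`subfrax` pipeline: what is simulated, how each stage computes its result,
and what the passing test suite does and does not demonstrate about real
patient data.

## Coordinate conventions

All volumes use array axes ordered (LR, AP, SI) with positive directions
patient-left, posterior, superior; world coordinates in mm
(`world = origin + index * spacing`); voxel indices 0-based.  Displacement
fields use the pull-back convention: `u` maps fixed-image coordinates to
moving-image coordinates, so a structure translated by `t` from fixed to
moving carries field value `t`.  NIfTI output maps (LR, AP, SI) onto the
RAS+ world frame as (−R, −A, +S).

## Synthetic cohort

**Anatomy.**  Organs are ellipsoids — prostate (semi-axes 20/18/22 mm) with
an embedded GTV, an anterior–superior bladder and a posterior rectum — on a
48³ grid of 2.5 mm voxels (smoke preset: geometry ×0.6 on 32³ × 3 mm).
The image assigns organ mean intensities, smooths boundaries (1.5 mm), and
adds a smooth random texture (SD 16 at 5 mm correlation length) plus voxel
noise (SD 3).  The texture is deliberately strong: the registration is a
contrast-pattern-matching method, and glandular/vesical texture is what
anchors its data term away from organ boundaries.  Realism is bounded by
what the DIR needs; MR pulse physics, rectal gas and peristalsis are out of
scope.  The texture and noise are baked into the session's MR1 and carried
through the deformations, so repeated scans of an unmoving anatomy are
identical; per-scan acquisition noise is not modeled (registration
robustness to run-to-run variation is exercised through the repeat jitter
instead).

**Intrafraction motion.**  Each interval (MR1→MR2, MR2→MR3 = shift 1,
MR3→MR4 = shift 2) draws a rigid CTV translation = per-patient systematic
offset + per-interval random draw.  Typical movers draw from a zero-mean
anisotropic normal; large movers from a two-component mixture (25% weight
on a 2.4× wider normal).  Per-axis SDs were calibrated once, numerically,
against the generative process itself so the pooled 3D magnitude matches
the cohort statistics the workflow reports: mean 1.0 mm / SD 0.6 mm
(typical), 1.9 / 1.5 mm (large movers), with systematic SDs 0.0/0.1/0.3 mm
in LR/AP/SI.  Matching SD/mean = 0.6 with pure normals forces strong SI
dominance (random SDs ≈ 0.14/0.40/1.04 mm); this is consistent with
bladder-filling drift being the dominant mechanism.  The large-mover
fraction defaults to 14/128 ≈ 11%.  The magnitude statistics constrain only
the 3D norm; the per-axis split is a modeling choice, stated here because
no per-axis intrafraction breakdown is available to calibrate against.

**Applying motion.**  MR2–MR4 are resampled from MR1 under a displacement
field `t·w(x) + (1−w(x))·b(x)`: `w` is 1 on the CTV (plus a pad of the
shift magnitude) and ramps to 0 over 12 mm, so the CTV moves rigidly and
its ground-truth centroid displacement equals the sampled translation to
within half a voxel; `b` is a radial Gaussian bladder-expansion bump used
for interfraction filling changes (amplitude drawn uniformly from 1–3 mm
per fraction, plus a prostate position offset with SDs 0.8/1.5/1.5 mm).
Images are interpolated linearly, labels nearest-neighbour.

**Seeding.**  One master seed; every (purpose, patient, fraction, interval)
gets its own `SeedSequence`-derived stream, so enlarging the cohort never
perturbs existing patients, and identical configurations are bit-identical.

## Registration

A variational intensity-difference method with diffusion-type
regularization, solved coarse-to-fine (3 pyramid levels, halving
resolution) with demons-style normalized updates:

    du = −(M(x+u) − F(x)) ∇F / (|∇F|² + diff²/step²),   u ← G_σ * (u + du)

with step 2 mm, Gaussian regularization σ = 1.5 mm, up to 100 iterations
per level, stopping when the 99th percentile of the update magnitude falls
below 0.05 mm (a volume-mean criterion would be diluted by the motion-free
background and stop prematurely).  Images are
band-pass filtered (1–12 mm) first so the data term responds to local
contrast patterns rather than absolute intensity.  Non-convergence within
the budget sets a flag on the result (propagated into provenance), never an
exception.

**Median of repeats.**  Because the solver can settle in nearby local
optima, production registrations are repeated (default 30×) from smooth
random initial fields (zero-mean, 0.2 mm SD, 4 mm correlation) and the
per-voxel, per-component median field is used.  The median is taken at
field level; this is a deliberate choice among plausible alternatives
(median of warped doses, median of final DVH values), made because the
field median keeps a single displacement consistent across all downstream
uses.  The repeat perturbation is initialization jitter only — the solver
is deterministic and vectorized, so there is no sweep-order randomness to
exploit.

**Contour guidance.**  For interfraction registration (day-to-day bladder
and rectum volume changes), squared differences of signed distance maps of
the bladder/prostate/rectum contours add demons-type forces, applied only
inside a ring extending (20, 20, 10) mm (LR, AP, SI) beyond the PTV, with
weight 1.  On phantoms where bladder contrast survives the day-to-day
change, the intensity term alone already aligns well; the guidance earns
its keep when the moving bladder is near-isointense with its surroundings
(the analogue of a filling-dependent signal change), which is the scenario
the guided-vs-unguided test exercises.

**CTV shift.**  The residual-motion estimate is the mean field vector over
the CTV voxels; shift 1 and shift 2 are differences of the cumulative
MR2/MR3/MR4 positions estimated against MR1.

## Protocol

Fraction colours come from the worst per-subfraction 3D shift magnitude:
green < 3 mm, orange 3–5 mm, red ≥ 5 mm by default, with an optional
per-axis red criterion.  These defaults are configuration values, not
reproductions of the clinical chart (which is institutional); they were
chosen looser than the 2–3 mm planning margins because a whole treatment
averages over ten subfractions while a single subfraction shift does not.
Fractions 1–3 are monitored; orange in fraction 3 extends monitoring to
fraction 4; red in a monitored fraction switches all *subsequent* fractions
to 5 mm isotropic margins (the switch is absorbing).  A fraction with
missing shift records is treated conservatively as orange and logged.

Cohort errors: Σ per axis = SD over patients of per-patient mean shifts;
σ = RMS over patients of within-patient SDs.  The naive Σ estimator
includes a σ²/n leakage term (≈0.03 mm at the defaults), which the
recovery tests account for explicitly rather than hiding.  Margins follow
the van Herk population recipe 2.5Σ + 0.7σ with configurable coefficients.

## Planning and dose model

CTV = prostate ∪ (GTV ⊕ 4 mm isotropic) minus bladder and rectum voxels.
PTV = anisotropic ellipsoidal-metric dilation of the CTV (tight preset
2/3/2 mm in LR/AP/SI; fallback 5 mm isotropic).  Dilations use scaled
Euclidean distance transforms, i.e. true ellipsoidal structuring elements
rather than per-axis box dilation.

The dose model is geometric: each 3.625 Gy subfraction plan delivers the
prescription uniformly inside the PTV with a Gaussian penumbra
`Rx·exp(−d²/2p²)` of the Euclidean distance `d` outside it, p = 3 mm
(≈5 mm 80–20% falloff, typical of MR-Linac prostate plans).  Treatment-
machine optimization is out of scope; the analysis needs plausible dose
gradients, not machine-accurate plans, and by construction D99%(PTV)
equals the prescription exactly.  Adapt-to-Position is a rigid resampled
translation of the planned dose to the estimated target position (ATP1 at
the MR2 position, ATP2 at MR3).  Large-margin plans differ from tight ones
only through the margin; prescription and penumbra are identical.

## Accumulation and DVH

Intrafraction: ATP1 is associated with the MR3 anatomy and ATP2 with MR4
(both acquired *during* the respective deliveries, which minimizes
underestimation of residual shifts); their dose maps are pulled back to MR1
through the median-of-repeats fields and summed.  Interfraction: fraction
2–5 MR1 scans are registered (contour-guided) to fraction 1 and the
per-fraction doses warped and summed there.  Dose warping is plain
pull-back interpolation without Jacobian weighting — dose is treated as an
intensive per-voxel quantity and the dose maps are warped directly.

DVH queries: Dp% is the dose received by at least p% of the structure
volume (interpolated order statistic of the voxel doses — the ICRU-style
near-minimum for p = 95/99); Dv cm³ is the minimum dose of the hottest
v cm³ and errors out, naming the deficit, when the structure is smaller
than v.  Accumulated OAR metrics are evaluated on fraction-1 contours (a
config switch selects daily contours instead) and are flagged in the
results as reliable only near the target, since contours are
guidance-corrected only inside the ring.

The counterfactual analysis re-plans post-switch fractions with the
original tight margins on the same anatomy with the same ATP shifts and
repeats the accumulation, giving per-patient ΔD99% between the delivered
and tight-margin scenarios.

## Problem sizes and fast paths

Default experiments run 8 patients at 48³ × 2.5 mm with 3 registration
repeats; the smoke preset runs 2 patients at 32³ × 3 mm with 1 repeat.
These sizes keep a full cohort run in the minutes range on one CPU while
leaving the registration errors (≤0.25 mm CTV-shift error for ≤5 mm
shifts at default resolution) well below the margins being studied.  The
simulator's ground-truth motions provide an exact fast accumulation path
(uniform translation fields instead of DIR), used by the scenario sweeps
and directional tests; its agreement with the DIR path is itself under
test, and the dose-conservation acceptance checks always run the full DIR
chain.

## Known limitations

* The phantom is ellipsoid-based; registration accuracy on real pelvic MRI
  (folds, gas, susceptibility) will be worse than on these phantoms, so
  passing recovery tests bound the algorithmic error, not the clinical one.
* Intrafraction motion is purely rigid for the target and the per-axis
  anisotropy of the motion model is a modeling choice constrained only by
  3D magnitude statistics.
* Rotations, seminal-vesicle motion, gating and drift correction are not
  modeled.
* The traffic-light thresholds are configurable defaults, not the clinical
  chart; absolute switch rates therefore have no claim to clinical
  fidelity, only the protocol *mechanics* do.
* OAR DVH values far from the target inherit the ring-limited contour
  correction and should be read accordingly.
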