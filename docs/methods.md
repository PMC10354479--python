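# Methods

This note records the models implemented in `pterowing`, the defaults
and why they were chosen, and what the synthetic validation does and does
not establish. Units are millimetres for skeletal lengths, metres for
wingspans at the pipeline boundary (the conversion happens once, at the
growth-series stage), and SI throughout the aerodynamic model.

## Measurement model

A specimen is a row of up to 13 positive lengths: skull, neck, tail,
humerus, ulna/radius, metacarpal IV, wing phalanges 1–4, femur, tibia,
and wingspan, defined osteologically as 2.1 × the summed length of the
seven wing-spar elements. Empty cells and `NA` mean "not preserved";
zero is never a missing marker because lengths are strictly positive.
For anurognathids the two distal phalanges are analysed as one merged
dimension (summed length, averaged sweep angle), reflecting uncertainty
about a separate fourth phalanx in juveniles.

## Multivariate allometry

Growth allometry is estimated from the covariance matrix of
natural-log measurements — covariance, not correlation, because
allometric coefficients are log–log slopes and correlation would erase
the scale information. With first unit eigenvector *u* (oriented to
positive mean) and p dimensions, the Jolicoeur coefficients are
AC_i = u_i √p, so an isometric dataset returns exactly 1 everywhere. An
alternative normalisation AC_i = p·u_i/Σu is available behind a flag;
both reduce to 1 under isometry and the choice does not affect the sign
of AC − 1.

Wingspan is included as an analysed dimension so the wingspan
coefficient b_z used by the extrapolation comes from the same
eigenvector as every b_y.

**Missing data.** Fossil tables are mostly incomplete (complete-case
analysis would discard nearly all specimens of large taxa), so absent
cells are completed before the PCA by iterative rank-1 EM: initialise at
column means, then alternately reconstruct absent cells from the best
rank-1 approximation of the centred matrix until the largest update
falls below 1e-8 (max 500 iterations). Rank 1 is the correct completion
model here because the generative structure of a growth series is a
single latent size axis; on noiseless log-linear data the scheme
restores deleted cells exactly, which the tests verify. Non-convergence
is reported, not raised.

**Uncertainty.** One-tailed 95% bounds come from a nonparametric
bootstrap over specimens (default B = 1000, type-7 percentile). For a
point AC below 1 the 95th percentile is reported as an upper bound —
the scientifically relevant question being whether the dimension is
*significantly* below isometry — and symmetrically the 5th percentile
for AC above 1 (AC exactly 1 reports the upper side). Classification:
`−` iff the upper bound is below 1, `+` iff the lower bound is above 1,
`=` otherwise. Bootstrap replicates that degenerate under resampling
(an all-absent column, zero variance) are discarded; more than 10%
discards is an error. Replicate imputations are warm-started from the
full-data completion, which changes nothing at convergence but cuts the
iteration count substantially.

## Growth extrapolation

Y₂ = Y₁ (Z₂/Z₁)^(b_y/b_z), evaluated in log space. This makes
extrapolation an exact one-parameter group (Z₁→Z₂→Z₃ equals Z₁→Z₃, and
round trips are identities to machine precision), which the property
tests assert. The trunk offsets L1 (shoulder to midline), L2 (hip to
midline) and L3 (shoulder–hip distance) grow isometrically (b_y = b_z).
The default grid is 0.3–7.0 m in 0.1 m steps with the seed wingspan
spliced in, so the series reproduces the seed specimen exactly at its
own wingspan. Seed measurements default to deterministic reference
specimens built from the per-taxon reference proportions (below). No
uncertainty is propagated from the coefficient bounds into the series:
extrapolation is deliberately a point operation.

## Planform geometry

Frame: x lateral, y anterior, midline at x = 0; sweep angles are
measured from the transverse axis with posterior sweep positive. The
shoulder sits at (L1, 0), the hip at (L2, −L3); the femur runs 45°
postero-laterally and the tibia parallel to the midline.

The trailing edge is a cubic Bézier with P0 at the ankle (ankle
attachment of the brachiopatagium), P3 at the wingtip and P2 = P3 so the
curve straightens into the tip. P1 is the intersection of a line through
the ankle at 30° to the tibia axis and a line through the wingtip at 30°
to the distal phalanx. Each "30° to a bone" admits two lines; the
implementation takes the ankle line that rises into the wing (the
membrane is deepest at the ankle) and the tip line tilted anteriorly
toward the body. This is the only sign choice that produces the
characteristic planform — deep proximal membrane tapering to a narrow
outer wing — with aspect ratios in the range reported for these taxa;
the all-posterior alternative yields implausibly deep wings (aspect
ratios ≈ 4–6). The construction is mirror-equivariant (the wing side is
inferred from the tip–ankle offset), and a control point falling outside
the root–tip lateral interval is a geometry error at planform-assembly
time.

Areas use the shoelace formula on the closed outline (midline → shoulder
→ leading-edge joints → wingtip → 1024 Bézier samples → ankle → hip →
midline), with simplicity validated independently by a polygon library;
wing area is twice the single-wing area (the half-trunk strip to the
midline is included; the uropatagium is excluded, as its shape is not
quantitatively constrained). Aspect ratio is Z²/wing area with Z the
nominal grid wingspan. At 1024 samples the discretisation error is
below 0.01%.

**Postures** ship as editable YAML: per-element sweep angles
approximated from published skeletal reconstructions (an anterior-sweep
pose shared by *Pteranodon*, *Sinopterus* and *Pterodactylus*; a
broader-wing pose for *Rhamphorhynchus* and anurognathids; a neutral
pose with the leading edge essentially perpendicular to the body axis).
They are configuration, not ground truth: absolute areas and
aspect-ratio endpoints move by tens of percent under defensible
alternative poses, while the *directions* of ontogenetic change are set
by the allometric coefficients and are robust to posture — the tests
assert trend directions under both pose families, not endpoint values.

## Mass and flight performance

Body mass: M = a Z^b with (a, b) = (0.681, 2.807) / (0.519, 2.550)
(one approach) and (0.3, 2.74) / (0.315, 2.56) (the other), for
non-pterodactyloids / pterodactyloids respectively. Wing loading is
M/S (kg m⁻²).

The flight model is a self-contained actuator-disc formulation:

- induced power P_ind = k(Mg)²/(2ρV·S_d), with disc area S_d = πZ²/4
  and induced-power factor k = 1.2;
- parasite power P_par = ½ρV³·S_b·C_Db, with body frontal area
  S_b = 0.00813·M^0.666 m² and body drag coefficient C_Db = 0.1;
- profile power P_pro = (X1/AR)·P_am with X1 = 8.4 and P_am the minimum
  of P_ind + P_par, held independent of speed (the classic
  approximation), so the minimum-power speed has the closed form
  V_mp = (A/3B)^¼, A = k(Mg)²/(2ρS_d), B = ½ρS_b·C_Db.

Air density is fixed at 1.225 kg m⁻³ (no altitude model) and
g = 9.81 m s⁻². All constants are conventional flight-mechanics defaults
and are exposed in `AeroConfig`. The public API finds V_mp by bounded
scalar minimisation on [0.1, 200] m s⁻¹ (tolerance 1e-6; a minimiser at
a bound means the configuration is unphysical and raises); the closed
form serves as an independent oracle in the tests. Derived indices:
D = P(V_mp)/V_mp, P_BMR = 3.277·M^0.624 J s⁻¹, COT⁻¹ = V_mp·M/P_BMR,
V_z = D·V_mp/(Mg), glide ratio V_mp/V_z (= Mg/D). The efficiency index
uses basal, not flight, metabolic power in the denominator, and the
glide ratio uses V_mp as the forward speed; both choices follow the
printed definitions of the indices, and sensitivity to a best-glide
speed instead of V_mp is left to the user via the power curve.

Because these aerodynamic outputs depend on a model family rather than
a closed set of published constants, validation is property-based: the
power curve is U-shaped, V_mp matches the closed form to 1e-4 relative,
V_z·Mg equals P(V_mp) to 1e-9 relative, and along every preset growth
series wing loading, COT⁻¹, sinking rate and glide ratio all strictly
increase with wingspan under both mass approaches and both pose
families — including the characteristic joint increase of glide ratio
and sinking rate (faster, not flatter, gliding with growth).

## Pairwise comparison

Performance trajectories of two taxa, paired at identical grid
wingspans only (no interpolation), are compared with a sign-flip
symmetry test on the mean paired difference: exact enumeration of all
2ⁿ sign patterns for n ≤ 20, seeded Monte-Carlo with add-one correction
(default 10⁵ draws) above. The mean was chosen as the statistic because
the grid supplies a few dozen pairs, making exactness cheap; the
p-value is two-sided and includes the observed arrangement, so it is
never zero. Under a symmetric null the rejection rate at α = 0.05 is
calibrated (≈0.051 at n = 12; slightly above the nominal level only
through the discreteness of the 2ⁿ lattice).

## Synthetic data: what it emulates and what it does not

The generator draws a latent log-size uniformly over the interval that
maps onto a configured wingspan range (log-uniform, so small and large
individuals are balanced as in a size-spanning ontogenetic series),
sets each log measurement to intercept + slope × size + N(0, σ²), and
deletes cells independently at the missing rate (MCAR). Wingspan is
generated as a measured dimension with its own slope — matching its
role in the PCA — never deleted, and clipped into the configured range,
which plays the role of the observed sample extremes; the 2.1× formula
applies to the wingspan-computation operation, not the generator.

Preset coefficient vectors equal published multivariate estimates for
the five studied ontogenetic series. The published table reports 10 of
the 13 analysed dimensions, and those 10 values alone do not satisfy the
Jolicoeur gauge Σb² = p; the presets therefore complete each vector with
skull/neck/tail slopes that restore the 13-dimension gauge exactly,
ordered skull ≥ neck ≥ tail to agree with the reported positive
skull/neck allometry where known. Without this completion the population
coefficients of the generative model would be the published values
rescaled by up to ≈5%, and no estimator could recover the published
numbers even from noiseless data. Per-taxon noise σ (0.03–0.065) was
calibrated, once, so bootstrap bound widths at the historical sample
sizes (88/22/10/59/12 specimens) are comparable to the published
confidence bounds; sample sizes and wingspan ranges mirror the published
series. Reference proportions (element lengths as fractions of the spar
at a reference size) and trunk fractions are approximations from
published skeletal reconstructions and fix only intercepts, never growth
exponents.

What passing tests show: the estimator chain (imputation → PCA →
bootstrap → classification → extrapolation → geometry → aerodynamics) is
correct on data whose generative structure matches the allometric model,
at realistic sample sizes and noise. What they do not show: robustness
to element-biased (taphonomic) preservation — real fossil distal
phalanges are lost far more often than proximal elements, which is why
published per-dimension confidence bounds within one taxon vary by an
order of magnitude while the MCAR generator produces roughly uniform
bound widths. Consequently a minority of published isometry/allometry
class cells (those encoding dimension-specific uncertainty, plus one
razor-edge wingspan cell whose printed bound coincides with its point
value) are not reproducible under this generator; the quantitative
coefficients themselves are recovered to well within ±0.05, with the
largest systematic deviation (≈0.03 on the *Pteranodon* wingspan slope)
traceable to range-clipping of the narrowest size range. Simulation
sizes throughout the test suite (5–20 seeds, B = 600–1000, n = 60–400)
were chosen to keep the whole suite in a few minutes on one CPU while
leaving order-of-magnitude headroom between measured margins and
asserted tolerances.

## Known limitations

- 2-D planforms only: no camber, no propatagium, no membrane tension or
  3-D wing-bone placement; one membrane attachment variant (ankle).
- Point extrapolation: coefficient uncertainty is not propagated into
  planforms or performance.
- The actuator-disc model omits flapping kinematics, anaerobic power
  limits, soaring environments, and agility/manoeuvrability indices.
- No multiple-testing correction across pairwise comparisons (by
  design), and no asymptotic permutation approximation.
- MCAR missingness only; no size- or element-dependent preservation.
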