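# Methods

This note documents the generative model behind `ichvol`'s synthetic
cohorts, the calibration of every default, the numerical conventions of the
statistical procedures, and what the passing test suite does and does not
establish about real imaging data.

## 1. Phantom model

A phantom is a 3D integer label grid (0 background, 1 ICH, 2 IVH,
3 distractor) with per-axis spacing in mm.  Voxel `i` along an axis with
spacing `s` is centred at `(i + 0.5)·s`; the third axis is axial; no affine
rotation is modelled.

**ICH shape.**  Each haematoma starts as an axis-aligned ellipsoid with
in-plane-dominant aspect ratios (semi-axis ratios drawn uniformly from
1.15–1.45 : 1 : 0.65–0.85) scaled to the target volume, then deformed by a
radial warp `r → r·(1 + 0.3·irregularity·f(u))`, where `f` is a unit-RMS
band-limited angular noise field (a superposition of 12 plane-wave cosines
with wave numbers 3–8 restricted to the unit sphere).  The warp preserves
star-shapedness, so the deformed lesion stays a single connected component;
digitization slivers are removed by keeping the largest component.  The
field is clipped at a per-realization bound probed on 2048 Fibonacci-sphere
directions, which also bounds the grid padding.  No published shape model
for ICH exists; any smooth single-component deformation family would do —
this one was chosen because its irregularity parameter monotonically
increases the surface-to-volume ratio and the maximal Feret diameters, the
two properties that drive ABC/2 bias.

**Volumes.**  True ICH volumes are log-normal with `mu = ln(median)` and
`sigma = ln(q75/q25) / (2·0.67449)` (0.67449 = standard-normal 75th
percentile).  Defaults: median 26.0 mL, IQR 9.3–59.2 mL, giving
`sigma ≈ 1.372`.  Note that a log-normal pinned at the median can reproduce
the IQR *ratio* but not both quartiles unless `median² = q25·q75`; the
calibrated distribution's own quartiles are 10.3 and 65.6 mL.  The sampled
volume is a target; the recorded ground truth is the voxel-count volume of
the realized mask (exact by construction).

**IVH, location, irregularity.**  IVH is present with probability 0.5
(reported prevalences straddle 49–51 %; 0.5 is the configurable default)
and occupies a uniform 5–40 % of the ICH volume, grown as a contiguous
label-2 region from a random contact voxel on the ICH surface (nearest
background voxels by Euclidean distance, topped up if clipping disconnects
the ball; achieved volume within 10 % of target).  Locations are
basal-ganglia/thalamus with probability 0.66; basal-ganglia cases draw
irregularity from the lower half of the configured range (default 0.1–0.8)
and lobar cases from the upper half, encoding the observation that deep
haematomas tend to be more ellipsoid.

**Grids and reslicing.**  Phantom grids default to 1 mm isotropic and are
auto-sized per case to hold the warped lesion plus IVH headroom (a fixed
grid may be configured, in which case infeasible cases raise with their
case id).  Auto-sizing was preferred over a fixed 128³ default because the
log-normal volume tail would otherwise make a fixed grid either wasteful
for the median case or infeasible for the upper percentiles.  Axial
reslicing to 3 or 5 mm aggregates slabs by majority label with ties broken
1 > 2 > 3 > 0, preserving the measurand.

**Distractors.**  1–2 mL ellipsoidal label-3 blobs on plain background away
from the lesion, plus an optional one-voxel rim shell — generic stand-ins
for dura, skull base and calcification hyperdensities.  Cohort masks do not
include distractors by default; the automated-segmentation error model
accounts for distractor inclusion parametrically.

## 2. Volumetry

**Voxel reference** — label-1 voxel count × voxel volume.  This idealizes
semi-automatic threshold segmentation as error-free; IVH (label 2) is never
counted as ICH.

**ABC/2** — reference slice = largest-area axial slice; A = maximal
pairwise distance between label-1 voxel centres on that slice (the digital
analog of a ruler); B = maximal extent of the same slice's voxel centres
along the perpendicular of A's direction (B ≤ A by construction); C =
slice thickness (cm) × slice count, where the Kothari-weighted rule counts
slices with area > 75 % of the reference slice fully and 25–75 %
(boundaries: ≥ 25 % half, > 75 % full) as half, and the full-extent rule
counts every slice containing ICH.  Volume = A·B·C/2 exactly.

Voxel centres rather than voxel footprints are used deliberately: the
maximum over many near-extreme boundary voxels already converges to the
continuum caliper from below, and on the benchmark ellipsoid
(30, 20, 10 mm semi-axes at 0.5 mm) the centre-based measure lands within
0.004 of the analytic full-extent ratio 3/π ≈ 0.9549.  A footprint-corner
variant was evaluated and rejected: corner inflation rewards slightly
tilted diameter pairs and biases B upward by ~1.5 %.  Whether study readers
measured B on A's slice or anywhere in the stack is not documented in
published SOPs; same-slice (standard Kothari practice) is implemented.

The Kothari-weighted analytic ratio on an ellipsoid is
`(3/π)·(1 + (√3 − 1)/2)/2 ≈ 0.6523` (integrating the elliptical area
profile `1 − (z/c)²` against the weight bands): the weighted C rule
*under*-measures perfect ellipsoids by design.  Consequently, on this
package's smooth shape family, ABC/2 with the default Kothari rule has a
net negative bias versus the voxel reference, while its bias still
*increases* monotonically with irregularity (the mechanism by which ABC/2
overestimates irregular haematomas in clinical series).  The package
reproduces the mechanism, not the net sign observed in any particular
patient cohort — real haematomas are not radially warped ellipsoids.

**Automated-segmentation error model** — parametric in the case's true
volumes:

| parameter | default | rationale |
|---|---|---|
| detection | `P = expit(−2.980 + 1.822·ln V)` | fitted so the default cohort yields ≈ 83 % detection (250/300 pattern) with a slope of 2.5 per SD of log-volume; missed-case median ≈ 5 mL vs ≈ 34 mL detected |
| `p_ivh_include` | 131/148 | IVH segmented in 131 of 148 IVH cases |
| `p_partial`, fraction | 0.22, U(0.2, 0.6) | partial segmentation in 55/250 detected cases; the lost fraction is not reported — 20–60 % chosen |
| `p_distractor_include`, volume | 0.4, U(0.5, 3.0) mL | frequent small extra hyperdensities |
| `multiplicative_noise_sd` | 0.25 | residual log-scale scatter of automated vs reference volumes |

Missed detections are recorded as *missing*, not zero, matching
complete-case analysis.  A purely logistic detection model cannot push the
missed-case median all the way down to 3.5 mL at 83 % detection without a
near-threshold slope (clinically, part of the missed cases are
volume-independent technical failures); the defaults keep a realistic slope
and accept a missed median near 5 mL.  `AutoSegErrorModel.error_free()`
disables every failure mode.

**ABC/2 reader noise** — A and B each scaled by `exp(N(0, reader_sd))`, C
jittered by one half-weight step with probability `min(1, 4·reader_sd)`.
Default `reader_sd = 0.10`: on the default cohort's volume spread this
produces a one-way ICC ≈ 0.97, the level of inter-observer agreement
reported for ABC/2.

## 3. Agreement statistics

Differences are `method1 − method2` with the reference as method2 where one
is present (positive = overestimation).  Percent differences use the
pairwise mean `(m1 + m2)/2` as denominator (the standard Bland–Altman
percent convention).  LoA = mean ± 1.96·SD (n−1 SD; z fixed at 1.96, not a
Student-t variant).  Heteroscedasticity screen: Kendall τ_b between
|difference| and pairwise mean — absolute differences, tie-corrected;
τ > 0.1 triggers the natural-log transform, retained only if τ decreases;
retained log limits `l` are back-transformed to mean-dependent limits
`slope·X` with `slope = 2(e^l − 1)/(e^l + 1)` (inverse
`r = (2 + slope)/(2 − slope)`).  Samples in which τ is undefined (all
differences tied, e.g. error-free pairs) are treated as homoscedastic.  The
back-transform is verified against binned empirical 2.5/97.5 percentiles at
n = 100,000 rather than trusted as algebra.

ICC is the one-way random-effects single-measurement form with the
unbalanced mean group size `k̄ = (N − Σk_i²/N)/(n − 1)` — chosen because a
repeat-reading design with different reader subsets per scan has no
crossed-rater structure; it is cross-checked against an independent
implementation (ICC(1,1)) in the tests.  No multiple-testing correction is
applied anywhere.  Subgroups: IVH presence, location, and a 40 mL split on
the reference method's measured volume; strata with < 3 complete pairs are
reported as not estimable.  The acceptability rule is boundary-inclusive:
percent LoA within ±10 % (both limits).

## 4. Sample size for limits of agreement

The study succeeds when both LoA confidence bounds lie inside (−δ, δ);
the bound half-width uses the standard approximate LoA standard error
`SD·sqrt(1/n + 1.96²/(2(n − 1)))` with a two-sided t critical value.
`loa_power` integrates the joint probability exactly under the normal model
(chi-square distribution of the sample SD × normal distribution of the
mean, midpoint quadrature on 4000 probability points); `power_by_simulation`
applies the identical decision rule to simulated studies and agrees within
0.006 on the tested grid.  Infeasible configurations
(`|mu| + 1.96·SD ≥ δ`) are reported as such instead of as an absurd n.
All parameters are exposed rather than hard-coding any particular study's
inputs, whose exact parameterization is typically ambiguous in print.

## 5. Pipeline and problem sizes

`run_study` measures every case with the three methods, adds two extra
ABC/2 readers on a ~10 % subsample for the ICC, runs all analyses for the
requested pairs × modes × strata and serializes a deterministic JSON report
(sorted keys, NaN-free, validated by the shipped `report_schema.json`).
With `generate_masks=False` no grids are rasterized: the voxel reference
equals the exact ground truth and ABC/2 is unavailable.  This parametric
mode is statistically identical for the automated-vs-reference comparison
(the voxel reference differs from the analytic truth only by
sub-voxel-volume discretization) and runs in ~0.1 s per 300-case study; it
is used for the 20-seed calibration sweep, while the fully rasterized
three-method study (~80 s at n = 300, 1 mm grids) is run once in the
acceptance script.  Test problem sizes (n = 300 cohorts, 200-seed
procedure-rate checks, 500-rep ICC recovery, 20,000-rep power oracles)
match the scales at which the corresponding properties are stated.

## 6. What the synthetic cohort does and does not show

The generator reproduces the *statistical structure* of a consecutive ICH
cohort (volume distribution, IVH prevalence, location mix, slice
thickness) and the *documented failure phenomenology* of automated
segmentation.  It does not model brain or ventricular anatomy, Hounsfield
intensities, scanner noise, or segmentation algorithms operating on images;
distractor geometry is generic; IVH geometry is a contiguous blob, not a
ventricular cast.  Passing tests therefore establish that the statistical
machinery is correct and that the documented failure modes produce the
reported agreement patterns (heteroscedastic overestimation concentrated in
IVH cases, missingness concentrated in small haematomas, failed ±10 %
acceptability) — they do not validate any particular segmentation product
on real scans, and numeric agreement values from synthetic cohorts should
not be compared digit-for-digit with any patient study.
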