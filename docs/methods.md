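# Methods

`myotrack` implements a longitudinal quantitative-MRI (qMRI) analysis of
thigh muscle for slowly progressing neuromuscular disease (the motivating
application is spinal muscular atrophy, SMA): per-voxel estimation of fat
fraction, water T2 and diffusion-tensor metrics; matching of per-muscle
segmentations between a baseline and a follow-up session; and a
mixed-effects model of the one-year change.  Because patient scans of this
kind are not publicly depositable, the package ships a digital thigh
phantom whose statistical structure mirrors the cohort conditions and
whose ground truth every estimator is validated against.

## Signal models and estimators

### Dixon / IDEAL fat-water separation (`myotrack.dixon`)

The 4-echo complex gradient-echo signal is modelled per voxel as

    S(t) = (W + F·φ(t)) · exp(i·2π·ψ·t) · exp(−R2*·t),
    φ(t) = Σ_k c_k exp(i·2π·f_k·t),   Σ c_k = 1,

with complex water and fat amplitudes (W, F), field offset ψ (Hz), one
common effective decay R2* (four echoes cannot support separate water and
fat decays), and a standard six-peak fat spectrum at 3 T (shifts −3.80,
−3.40, −2.60, −1.94, −0.39, +0.60 ppm; relative amplitudes 0.087, 0.693,
0.128, 0.004, 0.039, 0.048, normalised).  The simulator and the fitter
share this spectrum; a mismatch experiment only requires passing a
different `FatSpectrum`.

Estimation is variable projection: for a candidate (ψ, R2*) the amplitudes
solve a 2×2 complex least-squares in closed form, so only two nonlinear
parameters are searched.  A coarse grid (ψ ∈ [−200, 200] Hz step 5, R2* ∈
[0, 0.2] /ms step 0.01) produces per-voxel residual profiles; water–fat
swaps from ψ-aliasing are suppressed by quality-guided region growing
(each voxel's candidates are the local minima of its profile; growth
starts at the least ambiguous voxel and neighbours adopt the candidate
closest to the already-assigned field), followed by three 5× grid-zoom
refinements (final resolution 0.04 Hz, 8·10⁻⁵ /ms; single-voxel fits can
request more zoom levels).  Fat fraction is |F|/(|W|+|F|), a fraction
internally and a percentage in all tables.

### EPG water-T2 mapping (`myotrack.t2epg`)

The 17-echo multi-echo spin-echo train (ΔTE 7.6 ms, nominal 90°/180°) is
modelled with the extended-phase-graph (EPG) recursion over configuration
states (F⁺, F⁻, Z), truncated at order n+2 (higher orders cannot refocus
within the train).  The acquisition applies no fat suppression, so each
voxel is a two-compartment mixture

    S_n = M0 · [(1 − ff)·EPG(T2w, B1)_n + ff·EPG(T2f, B1)_n]

with the fat T2 fixed (default 150 ms — not identifiable from 17 echoes)
and fat T1 365 ms / muscle T1 1400 ms fixed (trains are weakly
T1-sensitive at TR ≫ T2).  The echo timing follows the CPMG reading
TE_n = n·7.6 ms; the printed protocol's first-echo entry is read as the
echo spacing of a uniform train, the only self-consistent interpretation.

Fitting is variable projection over a (T2w, B1) dictionary (T2w 5–150 ms
step 1, B1 0.5–1.2 step 0.02; amplitudes by closed-form non-negative
least squares), refined by alternating T2w/B1 line searches that shrink
the window 5× per level (~0.01 ms final resolution).  Magnitude trains
are invariant under B1 → 2 − B1 (refocusing angles mirrored about 180°),
so B1 is reported up to that reflection; T2w and ff are unaffected.
Voxels with fitted ff ≥ 0.99 carry no water information and are flagged
invalid.  With a known noise level, voxels below SNR 5 are flagged rather
than fitted (the Gaussian approximation to the Rician likelihood fails
there).  Joint per-voxel ff estimation is the default; `fit_t2` accepts a
mask/ff constraint if the Dixon FF map is to be imposed instead.  Slice-
profile integration across the excitation slab is not modelled; the
`alpha_ex_deg`/`alpha_ref_deg` arguments are the hook for effective-angle
calibrations.

### Diffusion (`myotrack.dti`)

The 42-volume scheme b = 0(1), 1(6), 10(3), 25(3), 100(3), 200(6), 400(8),
600(12) s/mm² uses per-shell electrostatic-repulsion direction sets
(deterministically generated).  Processing: (1) local-PCA denoising with
the Marchenko–Pastur eigenvalue criterion in 5³ sliding windows (stride 2
by default, overlapping estimates averaged), which simultaneously yields
the noise σ map and hence the SNR map (mean b ≤ 25 signal / σ) used later
as a statistical covariate; (2) optional per-volume affine registration to
the mean low-b volume, with b-vectors rotated by the rigid part (polar
decomposition); (3) tensor estimation by iteratively weighted linear least
squares (weights = predicted squared signal, tolerance 1e−6, ≤10
iterations) wrapped in REKINDLE-style robust reweighting: Geman–McClure
IRLS on approximately signal-scaled residuals, outliers flagged at
|standardised residual| > κ = 6 (the method's published default), final
iWLLS on inliers; voxels with fewer than 7 inliers are invalid.  The
kurtosis term is omitted — b ≤ 600 s/mm² cannot support it — so the
robust machinery serves pure DTI, and all b-values enter the fit by
default (`drop_b_below` removes the IVIM-sensitive shells for sensitivity
analyses).  MD/FA come from batched eigen-decomposition with eigenvalues
floored at 1e−7 mm²/s for FA stability.

### Longitudinal mask alignment (`myotrack.align`)

Sessions are compared over exactly the common anatomy: the session-A
water image is registered to session B (similarity → affine → b-spline,
multi-resolution, 30 mm control-point spacing — unstated in the source
protocol, chosen as a standard soft-tissue value).  The first stage is a
similarity transform (rigid plus one uniform scale) rather than pure
rigid: limbs atrophy between sessions, and without the scale degree of
freedom the shrinkage aliases into a spurious shift along the thigh
taper.  The metric is normalised cross-correlation: the two water images
are the same modality, and mutual information (offered as an option)
proved less stable on piecewise-homogeneous muscle.  It is evaluated only
over the z-range both fields of view cover (known a priori from world
coordinates), with a two-slice guard margin — points leaving the moving
domain are silently dropped from the metric, so without the margin the
optimiser can "improve" the correlation by shedding end slices.  The
stage starts at identity — both sessions live in scanner world
coordinates, so grid centres must not be forcibly aligned when the field
of view was re-planned.  The b-spline
inverse comes from displacement-field fixed-point inversion (round-trip
residual is a QC output).  Implausible affine scaling (singular values
outside [0.8, 1.25]) raises an error rather than propagating garbage.

Masks are propagated in both directions with nearest-neighbour
interpolation (label integrity over smoothness) and each session's native
masks are restricted by voxelwise **intersection** with the propagated
counterpart.  The source description of this step uses the word "union",
but its stated purpose — removing non-corresponding regions — and the
accompanying illustration describe an intersection; a union would add
non-corresponding voxels.  Intersection is therefore the default and
`combine="union"` preserves the literal reading for sensitivity analysis.
Muscles with fewer than 50 matched voxels in either space (no published
value; configurable) are dropped from both spaces, keeping the retained
set symmetric.  Parameter maps are never resampled — only masks move, and
all statistics are computed in each dataset's native space.

### Summaries (`myotrack.metrics`)

Per subject × muscle × side × time-point: FF/T2/MD/FA means over in-mask
voxels (Dixon-grid masks transferred to the T2/DWI grids by nearest
neighbour through world coordinates), SNR median, and cross-sectional
areas: CSA = voxel count × in-plane voxel area / occupied slices; cCSA
discounts each voxel by its fat fraction, so cCSA/CSA ≡ 1 − mean FF by
construction.  Aggregation reproduces the published per-muscle table
layout (FF mean ± SD across measurements, CSA/cCSA column totals).  The
fat-fraction distribution summary uses fixed 2 %FF histogram bins, a
Gaussian KDE (bandwidth 2 %FF) with peak detection for the mode count, and
flags muscles whose mean FF is at or below the 30% threshold.

### Statistics (`myotrack.stats`)

Change over the follow-up interval is modelled per outcome with REML and
crossed random intercepts for subjects and muscle groups (adductors =
adductor longus/magnus + gracilis; hamstrings = both biceps femoris heads
+ semimembranosus + semitendinosus; quadriceps = rectus femoris + the
three vastii; sartorius keeps its own group label), the baseline level as
a fixed covariate, and per-muscle SNR added for the diffusion outcomes.
Inference is Wald with a normal reference at α = 0.05.

The model is estimated on paired changes.  With one measurement per
time-point, a literal two-row-per-muscle design with the muscle's own
baseline as a fixed covariate is rank-degenerate: the baseline rows
reproduce the covariate exactly, halving the residual-variance estimate
and inflating the type-I error of the Wald test several-fold.
Conditioning on baseline makes those rows deterministic, so all
information about the time effect lives in the changes, and the reduced
model

    change = β_t + β_b·baseline_c (+ β_s·SNR_c) + u_subject + v_group + ε

is the well-posed equivalent.  β_t is the baseline-adjusted mean change;
in the balanced single-group case it equals the mean paired difference,
and its Wald test is calibrated (verified empirically at α = 0.05).
Time-point means are reported as mean(A) with a subject-clustered SE and
mean(B) = mean(A) + β_t.  The "two random intercepts with an unstructured
covariance" phrasing of the source is internally inconsistent (two scalar
intercepts admit no unstructured matrix); crossed independent intercepts
are the closest well-posed model.  The muscle-group intercept indexes the
functional groups; a single-group subset falls back to a subject-only
intercept with a flag.  Degenerate data (zero residual variance) report
p = 1 for a zero estimate with a flag instead of 0/0.

Paired t-tests (clinical scores, muscle-group FF) use pairwise deletion
and report the complete-pair count; fewer than two pairs or zero-variance
differences yield NA with a flag.

## The phantom (`myotrack.phantom`)

What it emulates:

* **Anatomy** — 12 thigh muscles per side as a weighted Voronoi partition
  of a thigh disk; anatomically large muscles get heavier cells; muscle
  bellies drift (±14 mm over the stack) and taper along z; the thigh
  narrows toward the knee (−12% radius); a stylised signal-free femur
  with a non-monotone radius profile runs through the stack; and each
  muscle carries a proximal–distal FF gradient (±6 %FF, recentred per
  label so the true per-muscle mean is exact).  Without this longitudinal
  structure a near-cylindrical phantom leaves through-plane alignment
  unconstrained — worse, a monotone taper alone is *ambiguous* between a
  z-shift and the atrophy scale change, which real bony landmarks and
  intramuscular gradients disambiguate.
* **Grids** — Dixon 25 slices × 6 mm, T2 13 slices with 6 mm gap, DWI 25
  slices, at the acquisition's 1.5/3/3 mm resolutions.  The default
  in-plane matrix is 96 (144 mm field of view) so per-muscle per-slice
  voxel counts (~300 at 1.5 mm) match the cohort's reported
  cross-sectional areas; smaller matrices are available for fast tests.
* **Baseline FF** — a two-component mixture: low mode 0.25, high mode
  0.42.  Mode SDs are 0.05/0.07: at the nominal ~0.1 the mixture would be
  mathematically unimodal (separation 0.17 < 2σ) and the documented
  bimodal histogram could not arise.  The adductor longus and the short
  head of biceps femoris always draw from the low mode truncated at 0.30
  (they are consistently mildly infiltrated); other muscles fall in the
  low mode with probability 0.2, giving ≈1/3 low-mode mass.
* **Progression** — high-mode muscles gain 1.3 %FF/year over a
  13.1-month interval; low-mode muscles are static; a mild area loss
  (−0.23 cm²/year contractile CSA) shrinks the session-B thigh radius.
* **Repositioning** — rigid (±5 mm, ±3°; through-plane translation
  damped), an in-plane b-spline warp (2 mm amplitude, 30 mm knots;
  repositioning deforms a thigh mostly in-plane) and a one-slice
  field-of-view shift; the composite is invertible by fixed-point
  iteration (residual < 0.1 mm).
* **Signals** — Dixon: the IDEAL forward model with complex Gaussian
  noise (IDEAL consumes complex data); T2 train: the two-compartment EPG
  model with a smooth B1 field (±5%) and Rician noise; DWI: axially
  symmetric tensors about the muscle fibre axis (along the thigh with a
  small per-muscle tilt) matched to the true MD/FA, with Rician noise.
* **Clinical scores** — HFMSE (0–66), MRC sum (44–210), MRC thigh and
  per-group dynamometry, generated with zero mean change and test-retest
  noise so paired tests are null by design.
* **Reproducibility** — every noise stream is keyed by (seed, subject,
  session, sequence).

What it does **not** emulate: bone/vessels and partial-volume texture
(tissue values are constant within a muscle, which is what makes
end-to-end truth comparisons exact); fat infiltration gradients within a
muscle; susceptibility (EPI) distortion; slice-profile effects; real
segmentation error (labels are exact).  Passing tests therefore establish
estimator and pipeline correctness under the modelled physics, not
robustness to every artefact of in-vivo data.

A separate record-level generator feeds the statistical experiments
directly (no images): per-muscle baselines from the same mixture, the
slope applied per muscle, subject (SD 0.6 %FF) and muscle-group (SD 0.5)
change offsets, and i.i.d. measurement noise whose SD (2.5 %FF) is chosen
so the model SE of the time effect matches the published table's 0.39 at
the default design (SE² = 0.6²/10 + 0.5²/4 + 2·2.5²/240).

## Numerical and problem-size choices

* IDEAL zoom depth: 3 levels for maps, 5 for single-voxel experiments.
* EPG state space truncated at n_echoes + 2 (exact for this readout).
* Registration runs single-threaded so reruns are bit-identical.
* Tests and the acceptance script run phantoms at reduced matrices
  (32–48 in-plane) except for the registration quality checks, which use
  the default 96 matrix once via a shared fixture; statistical recovery
  uses 200 replicates and the type-I calibration 1000, matching the
  power needed for their ±0.1 / ±0.02 tolerances.

## Known limitations

* Dice of propagated vs native masks is bounded by rasterisation: even
  the true transform yields ~0.94 for small muscles at these voxel
  sizes, so a ≥0.90 floor is a tight criterion, not a loose one.  On the
  default phantom eleven of twelve muscles reach 0.92–0.97; the
  sartorius — at its realistic proportions the thinnest wedge in the
  cross-section — sits near 0.88, because the ~1 mm residual of the
  deformable stage costs a thin structure disproportionate overlap.
  Attempts to close this gap with finer control grids, denser metric
  sampling or longer optimisation consistently overfit and made the
  overall alignment worse.
* Registration accuracy is quoted per axis: sub-voxel in-plane (≤1.5 mm)
  and a fraction of a slice through-plane — slices are 6 mm thick, so a
  3-D error below the in-plane voxel is not a meaningful target.
* B1 is reported modulo the 2 − B1 mirror; a vendor B1 map would resolve
  it but is not part of the protocol.
* The mixed model assumes time-constant subject/group effects enter the
  change only; with two time-points this is unidentifiable from richer
  covariance structures, which is precisely why the source's
  "unstructured covariance" cannot be realised.
* Motion/eddy correction is affine per volume; susceptibility distortion
  is out of scope.
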