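# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `osteophylo`, module by module.

## Voxel microanatomy

**Binarization.** Grayscale volumes are thresholded with voxels ≥ t
counted as bone; `t` is either user-supplied or the Otsu
between-class-variance maximizer of the volume histogram.  Otsu is the
default because micro-CT bone/air histograms are strongly bimodal; a
numeric override exists because batch studies often fix one threshold per
scanner session.

**VOI geometry.** Volumes of interest are cubes (default) or spheres with
0-based voxel indexing and half-open bounds.  For humeral-head work the
edge length is a configurable fraction of the head diameter (default
50%); the literature this convention follows does not pin the exact
fraction, so it is an explicit parameter rather than a claim.  The
capitulum VOI center is constructed from articular landmarks: the
proximodistal midpoint first, then the center of the rectangle bounded by
the anterior and lateral capitulum edges, the maximal concavity of the
anterior articular surface (capitulum/trochlea junction), and the
posterior maximal extension at the mediolateral middle.  Specimens whose
VOI touches an epiphyseal line are excluded by a manual input flag, never
auto-detected.

**BV/TV** is the bone-voxel count over the VOI voxel count — exact on a
binary grid, hence the phantom checks demand equality (solid → 1.0) or
the generator's own calibration tolerance (±0.01 for random-field foams).

**Mean Tb.Th** follows the model-independent sphere-fitting definition:
local thickness at a bone voxel is the diameter of the largest sphere
lying entirely in bone that contains the voxel.  It is computed from the
Euclidean distance transform through openings with balls of decreasing
radius (a voxel first covered at radius r has thickness 2r).  Candidate
radii are the distinct EDT values, capped at 48 levels for large volumes
(quantile-subsampled; this only ever biases thickness down by less than
one level spacing).  Thickness is evaluated on the full bone mask and
averaged inside the VOI, so struts crossing the VOI face are not
truncated.  Discretization makes a digital sphere of diameter d measure
within about one voxel of d; tests use that tolerance.

**Global compactness.** Per transverse slice, the total cross-sectional
area is the region enclosed by the periosteal contour, recovered by a
morphological closing (disk, default radius 3 voxels — enough to bridge
nutrient foramina at typical scan resolutions) followed by hole filling;
the slice is padded before closing so cortices touching the image border
survive the erosion half, and the filled region is unioned with the bone
mask so compactness can never exceed 1.  Slices with no bone are flagged
and excluded from the means.  Mean global compactness and mean total area
are means over the remaining slices.

## Timetrees

Trees are rooted, strictly binary (polytomies are rejected at parse time
to keep the covariance construction unambiguous), with branch lengths in
Ma.  Depth is measured from the root; the root age is the maximum
root-to-tip depth, so extant tips have age 0 and truncated tips positive
age.  Newick parsing is delegated to dendropy; writing is exact to twelve
significant digits, and read(write(t)) preserves the covariance matrix to
well below 1e-9.

**Recalibration** moves one divergence to a stated age, adjusting only the
three adjacent branches; conflicts with the parent or child ages raise
errors rather than silently compressing branches.

**Fossil grafting** inserts a divergence node on the attachment clade's
stem edge.  Three rules: a fraction of the stem edge (measured from the
older, rootward node — the convention is documented because either end
could be meant), an explicit divergence age, and a node-pushing rule that
places the divergence at `fossil age + δ` (default δ = 1 Ma) for fossils
older than the clade's crown.  The implementation realises the pushed
divergence as a new stem node, keeping the tree binary and leaving crown
ages untouched.  The fossil's terminal branch is the divergence age minus
the fossil age and must be positive.

**Covariance.** `phylo_vcv` returns V with off-diagonals equal to
λ-scaled shared path lengths and the diagonal equal to tip heights,
unscaled.  Scaling only the off-diagonals is the correlation-structure
form of Pagel's transform; it guarantees positive semi-definiteness for
λ ∈ [0, 1] and keeps the diagonal meaningful as variance weights on
non-ultrametric trees.

## GLS with optimized λ

σ² is profiled out analytically; the profile (restricted) log-likelihood
is maximized over λ ∈ [0, 1] with bounded Brent iteration, and the
endpoints are always evaluated explicitly because the profile is often
monotone.  REML is the default criterion (the ML option is exposed);
coefficient tests are two-sided t-tests with n − p degrees of freedom on
the GLS standard errors, and the ANCOVA group effect is a Wald F-test on
the dummy block.  The residual sum of squares is floored at 1e-30 so an
exactly collinear (noiseless) response yields a finite log-likelihood and
a pseudo-R² of 1 instead of an arithmetic error.

**Pseudo-R²** is the likelihood-ratio form
`1 − exp(−(2/n)(logL_full − logL_null))` on ML log-likelihoods, reported
without the Nagelkerke ceiling correction by default — the response is
continuous, so the ceiling is 1 up to numerical noise; the ceiling variant
is available via an option and the report names which was used.  Full and
null fits each optimize their own λ; if the optimizer leaves the full
model below the null, the function warns and clips at 0.

**Body-mass imputation** regresses log10(mass) on log10(CSA) over species
with both known, and predicts for every species with a CSA (fossils
included, flagged `body_mass_imputed`); species lacking a CSA keep their
database mass.  Log10–log10 is the field's allometry convention; the
pseudo-R² is insensitive to the base.

**Size correction** takes residuals of PGLS(trait ~ log10 mass); with an
intercept present these are invariant to mass-unit rescaling, which is
tested to 1e-6.

p-values are reported raw (two-sided), with no multiple-testing
correction.

## Convergence (C1)

Each independent acquisition is collapsed to a single tip on its clade's
stem, carrying the arithmetic mean of its members' (size-corrected)
values and the mean member tip height; members must be monophyletic and
non-overlapping.  Ancestral states are ML reconstructions under BM —
computed as GLS conditional means, which for a Gaussian process coincide
with the joint maximizer; point states only, uncertainty ignored as in
the reference implementation.  Dmax includes tip states as candidate
endpoints, which fixes the C1 = 0 baseline for purely divergent tips.
With more than two focal tips, Dtip and Dmax are summed across all pairs
before the ratio; the per-pair decomposition is always reported.

The simulation null estimates the BM rate from the observed traits on the
collapsed tree (REML, i.e. the GLS quadratic form over n − 1) and draws
replicate tip vectors exactly from their joint normal distribution
N(μ̂, σ̂²C) via a Cholesky factor of the tree covariance — distributionally
identical to branch-by-branch simulation and two orders of magnitude
faster, which is what makes the 200-meta-replicate calibration suite
cheap.  p = (#{C1_sim ≥ C1_obs} + 1)/(n_valid + 1); the +1 avoids p = 0,
replicates with undefined C1 (zero denominator, a measure-zero event) are
dropped and counted, with a warning beyond 10%.  The default n_sim is
1000.  C1 is invariant to shifting and positive rescaling of the traits,
so the estimated rate affects only the (exact) null sampling, not the
statistic's scale.

## Synthetic study systems

The generator's defaults emulate the analysis' study conditions: a
155-tip pure-birth (Yule) tree scaled to a 160-Ma root — the span of the
deepest therian divergences — with 11 independent, non-nested
subterranean regime shifts placed by rejection sampling (matching the
"independent acquisitions" semantics), one of them flagged as the
extreme "talpid-like" clade.  Fossil tips are emulated by truncating
terminal branches by a uniform fraction in [0.1, 0.9].

Traits evolve by recursion along branches.  BM adds N(0, σ²t) per branch;
OU uses the exact transition density (mean θ + (x₀ − θ)e^{−αt}, variance
σ²(1 − e^{−2αt})/2α), so recovery tests carry no discretization error,
and reduces to BM as α → 0 (verified distributionally at α = 1e-8).
Default rates: σ² = 0.02 trait²/Ma and α = ln 2/25 per Ma (a 25-Ma
phenotypic half-life), giving a stationary SD of ≈ 0.6; regime optima 0 /
1.0 / 2.0 for background / subterranean / talpid-like, so the
subterranean shift is ≈ 1.7 stationary SDs and the talpid-like clade
overshoots it, as the empirical phenogram pattern suggests.  The
synthetic mass–CSA allometry is log10(mass) = 1.0 + 1.5·log10(CSA) plus
0.05-dex noise (near-isometry of mass with a cross-sectional area).
These values were fixed once as field-realistic conditions and are not
tuned.

Voxel phantoms: solid/empty blocks; plate stacks (slabs kept clear of the
volume faces so the distance transform sees both surfaces; gaps twice the
plate thickness); rod lattices (three orthogonal cylinder families,
spacing 4× diameter); and Gaussian-random-field foams — smoothed noise
(kernel σ = half the element thickness) thresholded by bisection until
the achieved BV/TV is within 0.01 of target.

What the generator does **not** emulate: diversified (birth–death)
sampling, measurement error, intraspecific variation, correlated evolution
between traits beyond the shared allometric term, partial-volume and
beam-hardening artifacts in scans, and anisotropic trabecular fabric.
Passing tests therefore demonstrate correctness of the estimators under
the stated models, not robustness to those real-data complications.

## Problem sizes and numerical choices

The calibration suites use 100-tip trees with 200 meta-replicates and 500
null simulations per replicate, 50 replicates for λ recovery, and 100/200
replicates for ANCOVA power/size — sizes at which the Monte-Carlo error
of the checked quantities is comfortably below the asserted tolerances.
Matrix work is done by Cholesky factorization throughout; the C1 engine
factors the tree covariance once and reuses it across simulated
replicates, and batches ancestral-state reconstruction as a single matrix
product over replicates.  Ties in Dmax need no breaking (max of absolute
differences); degenerate inputs (constant traits, empty VOIs, all-zero
slices) raise typed signals rather than returning NaNs.

## Known limitations

- λ is searched on [0, 1] only, not up to the tree-specific maximum.
- Only Pagel's λ is offered as a signal/error model (no OU-based GLS).
- C1 only; the C2–C5 decompositions and Wheatsheaf-type indices are out
  of scope, as are multivariate versions.
- Acquisitions must be monophyletic tip sets; paraphyletic acquisitions
  need a user-designated representative clade.
- NRRD I/O requires SimpleITK; TIFF + JSON sidecar is the primary format.
- The periosteal contour recovery assumes a roughly convex cortex per
  slice; deeply invaginated sections would need a larger closing radius.
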