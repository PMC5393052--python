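# Methods

This note documents the models, parameter choices, and numerical conventions
behind the pipeline, and what the synthetic-data tests do and do not
demonstrate about real data.

## Pipeline model

The unit of processing is one field of view (FOV). Stages are applied per FOV
independently; condition-level statistics pool the per-cluster records of all
FOVs of a condition. A FOV is discarded (and reported as such) if it contains
no usable fiducial bead.

### Drift correction

A fiducial bead is an always-on emitter, so a 1×1 µm² bin of the localization
histogram that contains one qualifies by covering nearly every camera frame.
Detection requires localizations in ≥ 0.8 × frames_total *distinct* frames and
a total count ≤ 1.5 × frames_total. The coverage test (rather than a raw count
test) matters at short acquisitions, where a bright blinking cluster can
accumulate as many localizations as there are frames without ever covering
them all; the upper bound drops bins where blinking emitters sit on top of a
bead, which would corrupt the track.

Each track (within-frame duplicates averaged) is smoothed by Gaussian-weighted
local *cubic* regression — weight σ = 200 frames, truncated at a window of 800
frames, evaluated at 50-frame knots and interpolated with a cubic spline.
Local-polynomial smoothing is used instead of a kernel mean because it
reproduces polynomial trajectories exactly, including at the ends of the
track, where a Nadaraya–Watson smoother is biased. For acquisitions shorter
than the 20,000-frame reference, the drift's features compress proportionally,
so `process_fov` scales the weight σ as 200 × frames_total/20,000 (clamped to
[20, 200] frames) with a 4σ window; the low-level functions keep the reference
defaults. Per-bead trajectories are re-zeroed to their own smoothed start
(removing absolute bead positions), averaged, and subtracted. On simulated
data (150-nm smooth drift, two beads, 10-nm precision, 20,000 frames) the
trajectory is recovered to ≈1 nm RMS; 5 nm is the acceptance bound.

### Filtering and merging

Quality thresholds (precision 30 nm, log-likelihood-ratio score 250, PSF width
175 nm) are strict inequalities: values exactly at the threshold are retained.
A localization violating several rules is tallied under each. The PSF-width
filter keeps only emissions from a thin in-focus axial slab, which is what
makes 2D imaging of a 3D nucleus meaningful.

Blink merging links localizations frame-to-frame by nearest-neighbor
association within 30 nm, bridging at most one dark frame. Ties go to the
older track and localizations are processed in table order, so linking is
deterministic. Each track collapses to one record: position is the
inverse-variance (1/precision²) weighted mean, combined precision is
sqrt(1/Σ(1/σ_i²)) — exactly the standard deviation of that weighted mean —
photons are summed (conserved exactly), and the frame is the track's first.
The paper trail for the merge rule is the linking radius and gap; the
combination rule (inverse-variance weighting) is this package's choice,
selected for statistical efficiency and testability.

### Clustering and gating

DBSCAN with ε = 90 nm and min_samples = 8, counting the point itself inside a
closed ε-ball (scikit-learn's convention; the brute-force oracle used in the
tests implements the same rule). Clusters with < 50 localizations are removed;
a cluster of exactly 50 is kept. Border-point ties depend on visit order;
with the deterministic input ordering used here results are reproducible, and
the test-suite comparison to the O(n²) oracle treats border ties as
equivalent.

### Registration, QC, DDR classes

Merged, drift-corrected localizations are binned into a 2D histogram with
half-open bins of side pixel_size/5 (108 nm/5 = 21.6 nm); the wide-field probe
image is upsampled ×5 by nearest neighbor (count-preserving, no interpolation
bias) and the offset is the argmax of their mean-subtracted FFT
cross-correlation. The stored offset is the vector *added* to localization
coordinates to overlay them on the wide-field frame. Registration must run on
drift-corrected data: with 150-nm drift still in the table the clusters are
smeared and the correlation peak is meaningless. Recovery is exact to one bin
for integer-bin translations and within one bin for the simulated ~50-nm
channel offset. The DDR channel reuses the probe-channel offset (the two
wide-field images are acquired back-to-back with no stage motion between
them, and chromatic offset is taken as zero).

QC keeps a cluster iff (1) ≥ 50% of its localizations fall on wide-field
pixels above the locus threshold, (2) its centroid is inside the nucleus mask
when one is supplied (skipped with a warning otherwise), and (3) the Pearson
correlation between the cluster's local histogram and the wide-field patch
exceeds r_min = 0.3. Thresholds come from Otsu's method, floored at
median + 5 robust σ so that an image with no real loci yields an empty mask
instead of a random bisection of shot noise. Clusters whose centroid lies
within 500 nm of an identified fiducial track are additionally rejected
(`fiducial_bead`): beads are bright in both the localization data and the
wide-field reference, so they pass criterion (1), and a human analyst — who
knows the bead positions — would discard them. All of these are automated,
deterministic surrogates for what was analyst judgment in the original
workflow; f_locus, r_min, and the none/partial/complete cutoffs
(f_lo = 0.1, f_hi = 0.9 on the fraction of localizations inside the DDR locus
mask) are declared parameters, not measured ones.

### Morphometrics

R_g = sqrt(1/N Σ‖r_i − r̄‖²) with equal weights — every localization counts,
no shape assumption. Convex hull area comes from Qhull; degenerate sets
(< 3 points or collinear) have area 0; the volume proxy is area^(3/2)
exactly. No precision correction is applied to R_g; for isotropic per-axis
noise σ the inflation is E[R_g²] = R_g,true² + 2σ², which the tests use as the
prediction when comparing recovered to planted sizes (the per-cluster RMS
merged precision is exported as `mean_precision_nm` for exactly this
diagnostic).

### Estimators

* Density ratio: ρ_L/ρ_S = (N_L/R_g,L³)(R_g,S³/N_S); upper bound uses
  (R_g,L − δ, R_g,S + δ), lower the converse; δ defaults to 0.005 µm, the
  typical experiment-to-experiment variation of a condition mean (the standard
  error itself is < 1 nm at ≥900 telomeres). δ ≥ either radius is an error.
  Ratios display at 2 significant figures; raw values are kept.
* Contour length: n_bp × 0.332 nm/bp (the common 0.34 is selectable),
  displayed at 3 significant figures.
* Compaction-in-length: contour / (2·R_g). Using the 2·R_g diameter as the
  folded extent makes this an upper bound.
* Summaries: mean/SD (ddof = 1), quartiles, Gaussian KDE with Silverman
  bandwidth (omitted for a zero-variance sample, which has no finite
  bandwidth), threshold fractions with strict ">", Spearman ρ for the
  R_g-vs-N association (flagged when n < 10 or a variable is constant).

## Synthetic-data generator

The generator emulates the acquisition the pipeline was built for; its
defaults are the study conditions.

| parameter | default | rationale |
|---|---|---|
| cluster shape | anisotropic Gaussian, axis ratio U(1, 2.5), random orientation | reproduces the ovoid heterogeneity of real telomere foci without extra structure |
| target R_g | N(68, 21) nm short / N(88, 23) nm long, clipped at ±3 SD | condition means and spreads of the short/long-telomere comparison |
| emitters per cluster | 60 | with the blink model, yields a few hundred merged localizations per cluster |
| blinking | on-time geometric, mean 2 frames; off-time mixture of geometrics, means 2 and 200 frames, weights 0.8/0.2 | the observed off-time shape: a sharp peak at the origin plus a long tail |
| photobleaching | survival 0.875 per on-frame (mean 8 on-frames total) | bounds localizations per emitter at short acquisitions |
| precision | gamma, mean 10 nm, shape 4 (per axis); the *applied* noise equals the recorded value | positive, right-skewed, mean matches the measured precision |
| PSF width / score / photons | N(150, 10) nm; χ²(45); log-normal, median 3000 | realistic inputs for the three quality filters |
| drift | smooth random walk (Gaussian-smoothed, σ = frames/20), max excursion 150 nm, zero at frame 1 | slow thermal/mechanical stage motion |
| fiducials | 4 beads, near centers of distinct 1-µm cells, ≥ 1.5 µm from clusters, one localization every frame | beads adhere anywhere in reality; keeping them resolvable isolates the drift readout |
| wide-field | 108-nm pixels, PSF σ 130 nm (probe) / 250 nm (DDR), Poisson noise over constant background; beads rendered 4× cluster weight; whole image displaced by the (50, 50) nm channel offset | typical 100×/EMCCD scale; DDR loci are larger than telomeres; the offset is what registration must recover |
| frames | 2,000 per FOV (20,000 in drift-specific tests) | scaled-down acquisition; see problem sizes below |

One integer seed drives everything through deterministically spawned
substreams; identical configuration + seed reproduces outputs bit for bit.

What the generator does **not** emulate: overlapping/fusing telomeres,
nonuniform nuclear background and out-of-focus haze, repeated-localization
artifacts at high emitter density, axial (z) structure, detailed photophysics
(triplet shelving, dye-dye interactions), camera fixed-pattern noise, or
analyst-level ambiguity in QC. Passing the recovery tests therefore shows the
*pipeline arithmetic* is correct under the stated physics — not that the
biological conclusions would survive every real-world artifact.

## Raw-frame localization stage

An optional entry point (`telostorm.localize`); the canonical route ingests
localization tables directly. Candidates are local maxima of a
difference-of-Gaussians band-pass (σ 1 and 2 px) above a threshold,
deduplicated within the 7×7 fitting window keeping the brighter. Each ROI is
fit by Poisson maximum likelihood with an isotropic 2D Gaussian plus constant
background (L-BFGS-B with analytic gradients, ≤ 50 iterations); precision is
the CRLB-style estimate from the Fisher information at the optimum, and the
goodness score is the likelihood-ratio statistic against the saturated model
(larger = worse, 0 for a perfect fit), so the 250 filter reads as an upper
bound. Monte-Carlo calibration: the reported precision matches the realized
RMS error within 20% at 5,000 photons. Frames before frame 500 are skipped by
default — early frames of a STORM movie have too many overlapping emitters
for single-molecule fitting. Solutions that stall at machine precision (line
search failure with a near-zero gradient) are accepted; genuinely
non-converged candidates are dropped and counted.

## Problem sizes

The simulated study runs 2 conditions × 16 FOVs × ~60 clusters (≥ 900
clusters per condition, mirroring the per-condition telomere counts at which
the condition means stabilize) at 2,000 frames per FOV; drift-recovery checks
use the full 20,000 frames with beads only. At these sizes the complete test
suite finishes in under two minutes on one CPU. The analysis scripts default
to 4 FOVs per condition for a quick narrative run.

## Known limitations

* 2D only: no axial drift, astigmatic PSF, or 3D metrics (axial drift is a
  hardware concern; the 175-nm width filter is the 2D proxy for focal
  sectioning).
* The density ratio treats a telomere as a uniform sphere of radius ~R_g; it
  is a ratio of coarse proxies, not a measurement of absolute density.
* The compaction factor depends on the declared conventions (0.332 nm/bp,
  2·R_g denominator); both are stated, and alternatives are selectable.
* QC surrogate parameters (f_locus, r_min, f_lo/f_hi) are design choices
  standing in for analyst judgment; on real data they should be audited
  against a manually reviewed subset before the automated labels are trusted.
* The merge step can link localizations of *different* emitters closer than
  30 nm in adjacent frames; within a dense cluster this slightly averages
  positions toward the local centroid. The effect is below the statistical
  noise at the study's densities but would grow for much denser targets.
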