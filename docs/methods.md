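# Methods

## Kinetic model

The analysis is purely semi-quantitative: no pharmacokinetic model
(Ktrans, Kep, Vp) is fitted. A series holds four aligned volumes; the
volumes used by the metrics are the pre-contrast `S0` and the
post-contrast volumes whose acquisition times are nearest 120 s (`S1`)
and 480 s (`S2`) — the middle (~300 s) volume is carried for format
fidelity only. Per voxel,

    PE  = 100 (S1 - S0) / S0        [%]
    SER = (S1 - S0) / (S2 - S0)     [unitless]

with the conventions:

- voxels with `S0 <= 0` have undefined PE and are excluded from every
  count, including the washout-fraction denominator;
- SER is evaluated only where PE >= 50%;
- where `S2 - S0 <= 1e-6 * S0` the contrast has cleared to (or below)
  baseline — the strongest washout — and SER is set to `SER_max = 10`;
  the whole map is additionally clamped at `SER_max`, because values
  just above the epsilon cutoff are otherwise unbounded and a single
  voxel could dominate a hot-spot window mean. The clamp is monotone
  and far above the 1.1 washout threshold, so no classification
  changes.

Per lesion: **peak PE** and **peak SER** are the maxima of 3×3×3
window means, searched over every voxel center; window means use only
defined in-mask voxels, windows with fewer than 14 such voxels
(majority-in-mask) are ineligible so near-surface peaks remain
reachable without background dilution, and ties resolve to the
lexicographically smallest (z, y, x) center for determinism. **FTV**
is the count of in-mask voxels with PE >= 50% times the voxel volume
(cm³). **WF** is 100 × (washout voxels, PE >= 50% and SER >= 1.1,
both thresholds inclusive) / (all defined in-mask voxels) — the
denominator is deliberately the whole tumor, not the enhancing subset.
Masks live on the image grid (0-based (x, y, z) indices, NIfTI axis
order); no resampling happens in the kinetics module. A 26-connected
region grower over PE >= 50% voxels is provided as segmentation
plumbing only.

## Phantom

`generate_lesion` embeds an ellipsoid of the requested radius in a
homogeneous background (baseline intensity 100 by default) and
partitions its voxels into washout / plateau / persistent classes with
exact rounded counts, arranged as concentric shells (washout
innermost, so the strongest class always contains a full 3×3×3 window
and the designed peaks are attainable). Signals are synthesized by
inverting the metric definitions —
`S1 = S0(1 + PE/100)`, `S2 = S0 + (S1 - S0)/SER`, the middle volume by
linear interpolation in time — so noise-free class targets are exact
by construction; independent additive Gaussian noise (not Rician; no
magnitude bias, B1/coil inhomogeneity or motion is modelled) is added
per volume. Default geometry follows a clinical protocol: 0.5 × 0.5 ×
1.3 mm voxels, timepoints 0/120/300/480 s. Default class kinetics
(PE %, SER) are washout (220, 1.9), plateau (160, 1.0), persistent
(110, 0.65) — peak PE around 200% and peak SER near 1.9, the scale of
values reported for invasive breast cancers.

`generate_cohort` draws half of the lesions around each of two
washout-fraction medians (defaults 22.5% and 50.6%, the reported
low/high-MVD group medians) with Gaussian spread 8 percentage points
(clipped to [1, 97]), radii uniform on 3–5 mm on a reduced 24×24×16
grid so cohort-scale simulation stays cheap, and noise sd 2. Expected
MVD is `5 + 0.4 × WF` with negative-binomial dispersion k = 10 —
overdispersed counts spanning roughly 8–56 with median near 17 — and
each of two readers observes the lesion count plus independent
Gaussian reading noise (sd 2), rounded and clipped at zero. All
randomness flows from one master seed through spawned per-lesion
substreams, so outputs are bit-reproducible and independent of
iteration order. The phantom is a study-condition stand-in, not a
reconstruction of any patient cohort: passing recovery tests shows the
pipeline is correct and calibrated under these conditions, not that
real lesions behave this way.

## Radiomics

Preprocessing z-scores the **whole volumetric stack** (not the mask)
to zero mean / unit variance, then resamples to 1 mm isotropic spacing
(trilinear for intensities, nearest-neighbor for the mask). Because
normalization absorbs any positive affine intensity transform, all
features are invariant to global offset and gain. In-mask intensities
are discretized with a fixed bin width of 0.25 in z-score units
(`level = floor((x - min)/w) + 1`); the source text states no bin
width, aggregation rule or interpolator, so these are declared package
choices recorded in the output metadata, with 0.25 z-units mirroring
the common bin width of 25 after a ×100 rescale of normalized MR.

The catalog holds exactly 108 names, frozen in a versioned manifest
(`catalog.json`): shape 14, first-order 19, GLCM 24, GLRLM 16, GLSZM
16, GLDM 14, NGTDM 5. Conventions:

- GLCM and GLRLM use the 13 unique 3D directions at distance 1;
  per-direction matrices (GLCM symmetrized) are computed separately
  and features averaged across directions. GLSZM zones and the GLDM /
  NGTDM neighborhoods use 26-connectivity; a GLDM neighbor is
  dependent when its level difference is ≤ 0 (i.e. equal), and the
  dependence size counts the center itself, so it is ≥ 1.
- Entropies use log base 2; every ratio or log argument carries an
  eps = 1e-16 guard. For a single-level region entropy- and
  variance-like features are 0, while Correlation and MCC take the
  conventional value 1.
- First-order Variance (and everything derived from it) uses the
  population (divide-by-N) convention; Kurtosis is non-excess.
  Entropy/Uniformity are computed on the discretized histogram.
- Shape: volume and surface area come from a marching-cubes mesh of
  the mask; the binary surface is smoothed with a 0.8-voxel Gaussian
  before meshing because a hard 0/1 surface is stair-stepped and
  inflates area ~9% (a fine sphere then scores sphericity > 0.99
  instead of 0.92). Axis lengths are 4·sqrt(eigenvalue) from PCA of
  physical voxel centers; 2D maximum diameters are the largest
  in-plane voxel distances per axial/coronal/sagittal plane;
  single-voxel masks report degenerate (0) axis features.

Every matrix-family feature is verified against an independent naive
implementation (explicit pair/run/zone/neighborhood enumeration and
scalar formula loops) on hundreds of random images, relative error
< 1e-8. Filtered feature banks (wavelet/LoG), 2D extraction and
scanner harmonization are out of scope.

## Statistics

MVD reader counts are merged as the mean unless the readers differ by
≥ 12, which raises an adjudication flag (a supplied consensus value
then replaces the mean). Dichotomization is low ≤ cohort median <
high, midpoint convention for even n. For each variable the battery
reports:

- **Wilcoxon rank-sum p** (two-sided): full enumeration of group
  assignments with midrank ties for combined n ≤ 12; the exact
  Mann-Whitney distribution for tie-free data up to n = 50 (the
  convention of R's `wilcox.test`, which keeps the test calibrated at
  cohort scale — the normal approximation rejects at only ~0.6–0.8%
  for a nominal 1% at n = 27); tie-corrected normal approximation
  otherwise. Significance flags use this p against the applicable
  alpha (0.0125 kinetics, 0.01 radiomics screen, with no further
  correction of the screen).
- **Odds ratio per 1 SD** from a univariable logistic fit (maximum
  likelihood; predictor scaled by the sample SD, ddof 1) with a Wald
  95% CI; perfect separation is detected up front and reported as an
  explicit flag with an unbounded CI instead of a divergent estimate.
- **AUC** as the Mann-Whitney pair statistic (ties count ½) with a
  95% CI from the DeLong structural-component variance applied on the
  logit scale (delta method). The logit scale matters at n ≈ 27: the
  plain normal interval covers a designed AUC of ~0.82 in only ~89%
  of replicates, the logit interval in ~95%. Degenerate AUC 0/1 falls
  back to the truncated normal interval.
- **Spearman r** (midrank ties) against continuous MVD, CI via Fisher
  z with variance 1.06/(n − 3), p from the t approximation.

Radiomics features are first passed through
`x -> sign(x)·log(1 + |x|)` and scaled to unit sample SD: several
catalog features (ClusterShade among them) are legitimately negative,
and this signed log is odd, strictly monotone and defined at 0, so it
tames skewness without touching any rank-based statistic. Per-variable
failures (constant features, degenerate fits) mark the row failed
rather than aborting the table. Multivariable modelling and survival
analysis are out of scope.

## Pipeline

`run_pipeline` derives everything from one `RunConfig` whose defaults
are the analysis constants (PE threshold 50%, SER washout 1.1, 3×3×3
window, alpha 0.0125 / 0.01) and one seed; outputs are a cohort CSV
(4 kinetic + 108 feature columns plus counts), the two association
tables, and a manifest with config snapshot, per-lesion status and
SHA-256 checksums. Identical config + seed reproduces every file
byte-identically. Lesion failures are logged and skipped; a run aborts
only when more than half fail.

## Verification design and problem sizes

The test suite checks, among others: noise-free phantom summaries
equal designed truth to 1e-9; hot-spot means against exhaustive window
enumeration; texture features against brute force on 200 random images
up to 6³ with ≤ 5 levels; AUC against pair counting for n ≤ 20;
exact Wilcoxon against full permutation enumeration for n ≤ 10;
binary-predictor logistic ORs against the contingency cross-product
ratio. Two calibration studies use the phantom cohort design at n = 27
(14 low / 13 high, WF medians 22.5/50.6):

- *Parameter recovery*: the designed AUC is estimated from a
  50,000-lesion design-level simulation; 500 seeded cohort replicates
  run the full image pipeline for WF, and the logit-DeLong 95% CI must
  cover the designed value in ≥ 90% of replicates.
- *Null calibration*: under a slope-0 MVD model the screen's flag
  rate at alpha 0.01 must lie in 1% ± 0.5%. Features from the same
  cohort are near-perfectly correlated through the phantom's latent
  washout and size variables, so sharing one MVD draw across the 108
  features makes the flagged fraction bimodal (almost always 0,
  occasionally ~half the catalog) and uninformative at any feasible
  replicate count; the calibration therefore pairs each feature-test
  with an independent null MVD draw — same null model, same screen,
  same estimand (per-test type-I error) — over 19 image cohorts × 108
  features × 5 draws = 10,260 tests (standard error ~0.1%).

These sizes are the package's chosen verification scale; the phantom's
reduced cohort grid keeps a full calibration run in the low minutes on
one CPU.

## Known limitations

- The phantom's class structure is concentric and its noise Gaussian;
  it does not emulate heterogeneous enhancement textures, motion, or
  partial-volume effects, so radiomics features across phantom lesions
  vary along few latent dimensions (washout burden, size).
- The printed 3×3×3 hot-spot volume at 0.5×0.5×1.3 mm spacing is
  8.775 mm³; the implementation reports true window geometry.
- Discretization and resampling choices are declared, not inferred;
  feature values are comparable only within a fixed configuration
  (bin width, target spacing, catalog version are therefore written
  into every output).
- Surface-area smoothing slightly erodes mesh volume (<2% for
  radius ≥ 6 voxels); voxel-count volume is reported alongside and is
  exact.
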