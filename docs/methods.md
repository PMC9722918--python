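# Methods

`mitorhythm` implements the quantitative chain of a circadian imaging
study of dendritic-cell mitochondria: confocal-style image
quantification of mitochondrial fission/fusion, rhythmicity statistics
on the resulting time courses, and the derived assay quantities that
usually accompany such a study (Mito Stress respiration parameters,
ΔΔCt fold changes, mask-restricted MFI). Everything runs on synthetic
data with known ground truth; this note records the models, the
defaults and the reasoning behind the open design choices.

## Cosinor model

For observations $Y_i$ at hours $t_i$ and fixed period $\tau$ (24 h),

$$Y_i = M + \beta\cos(2\pi t_i/\tau) + \gamma\sin(2\pi t_i/\tau) + \varepsilon_i,$$

fitted by ordinary least squares with replicates pooled (pooling keeps
the residual degrees of freedom for the F test; fitting to per-time
means is available by averaging beforehand). Derived quantities:
amplitude $A=\sqrt{\beta^2+\gamma^2}$ and acrophase
$\Phi=\operatorname{atan2}(\gamma,\beta)\,\tau/2\pi \bmod \tau$, the
literal peak time of the fitted curve. The arctangent form
$\tan^{-1}(-\gamma/\beta)$ sometimes quoted for the acrophase is
quadrant-ambiguous (it equals $-\operatorname{atan2}(\gamma,\beta)$
only up to $\pi$); `atan2` resolves the quadrant so that the fitted
maximum really occurs at $t=\Phi$, which is what a phase estimate is
for.

Rhythmicity is the F test of $H_0:\beta=\gamma=0$:
$F = \frac{(SS_0-SS_1)/q}{SS_1/(n-q-1)}$ with $q=2$ and $p$ from
$F_{q,\,n-q-1}$. Degenerate cases are defined, not crashed on:
constant data give $A=0$, $p=1$ and an undefined (NaN) acrophase; a
perfect rhythmic fit reports $p$ at the floor $10^{-15}$.

**Rank-deficient sampling designs.** Sampling a 24 h rhythm every 12 h
— a design circadian studies actually use — makes
$\sin(2\pi t/24)$ identically zero, so the design matrix has rank 2.
The fit uses rank-revealing least squares (`lstsq`/pseudo-inverse):
the unidentifiable coefficient is set to zero and the F test's
numerator degrees of freedom drop to rank − 1. Fewer than 3 distinct
times is a hard `SingularDesignError`; at least 4 distinct times are
recommended for a well-conditioned fit.

## JTK-style test

A deliberately minimal fixed-period variant of the JTK family: for
each candidate acrophase $\varphi$ on a grid with the sampling interval
as spacing, Kendall's tau (tau-b) is computed between the data and
$\cos(2\pi(t-\varphi)/\tau)$ at the observation times, with a one-sided
concordance p-value — exact enumeration when $n\le 9$ and no ties,
normal approximation otherwise. The reported p is the per-phase
minimum times the number of phases (Bonferroni), capped at 1; because
the phase references are strongly correlated this is conservative,
which the calibration check confirms (null rejection ≈ 4–5 % at
nominal 5 %). Period scanning, lag grids and meta-analytic
integration of multiple detection methods are deliberately out of
scope.

One numerical subtlety: reference values that are equal in exact
arithmetic (observations one period apart, or symmetric cosine values)
must be exact ties, or tau-b's tie corrections drift by machine
epsilon between phases and break the antiphase symmetry of the test.
The reference is therefore evaluated on times folded into one period
and rounded to 12 decimals before ranking.

## Synthetic data generators

The generators define the conditions every downstream claim is tested
under.

**Images.** One confocal-like slice per call: cells are disks of
radius 5 µm (default) on a dark background; mitochondria are capsules
— straight tubes of width 0.4 µm with semicircular caps, optionally
mildly bent along a quadratic Bézier — because capsules match tubular
mitochondrial morphology and have analytically known centreline length
and area. The reported true "length" is the end-to-end extent
(centreline + width). Object lengths are drawn per class — short
U(0.5, 0.9) µm, mid U(1.2, 2.8) µm, long U(3.3, 4.5) µm — with margins
to the 1 µm and 3 µm class boundaries so the true class is never
ambiguous under blur. The forward model is paint (anti-aliased, 1 px
soft edge) → Gaussian PSF blur (σ = 0.08 µm) → additive Gaussian read
noise (σ = 4 on a 0–255-ish photon scale) → clip at 0. Default
calibration is 0.1 µm/pixel, plausible for a 63× oil objective, and is
always explicit, never inferred from files. With `allow_touching`
off, capsule surfaces keep a gap of at least 2·PSF σ so that blurred
objects remain resolvable; placement failures raise an error naming
the cell rather than silently dropping objects. Not modelled, hence
not validated by these tests: 3-D structure, photobleaching, organelle
texture, uneven illumination, and cell-shape variability — real images
are harder than these fixtures, and the recovery rates measured here
are upper bounds.

**Time series.** $y(t) = M + A\cos(2\pi(t-\Phi)/\tau) + \varepsilon$,
$\varepsilon \sim N(0,\sigma^2)$ i.i.d. across times and replicates;
default sampling every 4 h over 48 h with 3 replicates, matching a
serum-shock synchronisation course.

**OCR traces.** Four plateaus (baseline, post-oligomycin, post-FCCP,
post-rotenone/antimycin A) with i.i.d. Gaussian noise, the standard
Mito Stress layout with ≥ 1 measurement per phase.

All generators are bit-deterministic given their spec (the seed is a
spec field).

## Segmentation

The macro-style recipe, fully automatic (no manual mask correction):

1. **Normalise** to the full 16-bit range (min → 0, max → 65535,
   round half up; constant images map to zero). Idempotent.
2. **Cell masks**: Gaussian smooth (σ = 1 µm), auto-threshold, fill
   holes, remove objects < 10 µm², optional distance-transform
   watershed to separate touching cells.
3. **Mitochondrial mask**: band-pass as difference-of-Gaussians with
   σ = 0.1 µm / 0.8 µm (the small σ about half the tube radius keeps
   the inter-object valleys deep; the large σ removes background),
   negative response clipped to zero. The auto-threshold (Otsu
   default, IsoData available) is computed over the *positive*
   response only: the clipped DoG has a large point-mass at zero that
   would otherwise drag the threshold down and bridge neighbouring
   objects. Objects < 0.1 µm² are removed.
4. **Split touching objects**: markers are h-maxima of the Euclidean
   distance transform with prominence ≥ 0.15 µm (≈ 1.5 px at default
   calibration; smaller values over-split tubes whose ridge
   undulates); watershed on the negated distance transform restricted
   to the mask. Components whose maxima are all shallower than the
   prominence keep their global maximum as a fallback marker, so the
   output labels always partition the input foreground exactly.
   Watershed flooding order (scikit-image) resolves boundary ties; it
   is deterministic, which is what reproducibility requires.
5. Restrict mitochondria to pixels inside cells; relabel contiguously.

All size parameters are physical (µm, µm²), so results are invariant
to pixel size up to discretisation (tested at 2× resolution).

## Morphology

Per object: area (pixel count × pixel area), length, aspect ratio
(best-fit-ellipse major/minor, minor floored at 1 px so 1-px-thin
objects stay finite), circularity $4\pi A/P^2$ clipped to ≤ 1 with a
weighted boundary-step perimeter estimator (a naive pixel-edge count
biases circularity low), centroid, mean intensity.

**Length convention.** The primary `length_um` is the maximum Feret
(caliper) diameter, i.e. the end-to-end extent. The best-fit-ellipse
major axis, the other common convention, overestimates a
uniform-density rod by the moment factor $2/\sqrt{3}\approx 1.15$
(measured ≈ +10 % on capsule fixtures) and would systematically
misclassify objects near the 1 µm and 3 µm class boundaries; it is
still emitted as `ellipse_major_um` for comparability. On noiseless
capsule fixtures the Feret length tracks ground truth within about
1 px + PSF σ.

Fission/fusion scoring: short < 1 µm, 1 µm ≤ mid ≤ 3 µm, long > 3 µm
(boundaries closed on the mid class, matching the "1–3 µm" reading).
The per-cell short fraction is the fission score and the long fraction
the fusion score. Per-cell summaries use even-count medians
(mean of central pair); cells with zero mitochondria are retained with
NaN medians — silently dropping them would bias per-timepoint means
toward mitochondria-rich cells.

## Assay quantities

Mito Stress: non-mitochondrial respiration = mean of the
rotenone/antimycin phase; basal = last baseline measurement −
non-mitochondrial (the last pre-injection point is the most
equilibrated; a mean-of-baseline option exists); maximal = max of the
FCCP phase − non-mitochondrial; spare capacity = maximal − basal,
also reported as 100·maximal/basal because the percentage convention
is common. A negative corrected basal is returned as-is with a
quality flag, never clamped.

ΔΔCt: per sample ΔCt = Ct(target) − Ct(reference gene);
ΔΔCt = ΔCt − mean ΔCt of the control condition per gene;
fold = $2^{-\Delta\Delta Ct}$. By construction control fold changes
geometric-mean to 1; the method is invariant to any uniform Ct shift.
Amplification-efficiency (Pfaffl) correction is out of scope.

## Pipeline

`run_morphology_timecourse` composes the stages over a
directory-per-timepoint layout (`t<hours>/`, or a manifest CSV which
wins on conflict). Aggregation unit is the cell: per-cell metric
values enter the rhythm fits as pooled replicates (preserving F-test
degrees of freedom), while per-timepoint tables report mean ± SEM over
cells; per-object pooling is available via config. The rhythm stage
runs on four metrics: fission fraction, fusion fraction, median
length, and mitochondrial MFI. MFI is measured on the *raw* image
(per-image 16-bit normalisation would erase the across-timepoint
intensity signal), while segmentation runs on the normalised image.
Unreadable images are recorded as per-file errors without aborting the
run; fewer than 4 distinct timepoints skips the rhythm stage with a
warning. The JSON/CSV reports carry a provenance block (hash of the
analysis-relevant config, package version, seed) and contain no
timestamps, so a rerun with the same config is byte-identical.

## Problem sizes and numerical choices

Validation workloads use single-cell 160×160 px fixtures (6–8 capsules
per cell), 100-fixture segmentation cohorts, 2000-replicate null
calibrations for both rhythm tests, 500-replicate parameter-recovery
simulations, and end-to-end courses of 5 timepoints × 20 cells
(planted rhythm: short-fraction mesor 0.35, amplitude 0.25, acrophase
12 h) and 25–50 null courses at 8 cells/timepoint — sizes at which the
binomial/Monte-Carlo tolerances in the tests are meaningful. Grid
searches validating the OLS cosinor use 201×201×241 (M, A, Φ) grids
via a quadratic expansion per phase. Normalisation rounds half-up on
the 16-bit scale; watershed uses 8-connectivity.

## Known limitations

- The synthetic image model omits most nuisances of real confocal data
  (see above); defaults were chosen for a clean MitoTracker-style
  preparation, and real images will need per-dataset tuning of the
  band-pass sigmas, threshold method and prominence.
- The JTK variant is single-period, cosine-referenced and
  Bonferroni-adjusted — a reduced form of the full JTK_CYCLE
  lag/period scan.
- The watershed prominence is a length (µm) on the distance transform;
  extremely curved or varicose tubes can still over-split.
- No multiple-testing correction across analytes by default
  (per-analyte p-values, as circadian screens usually report);
  Benjamini–Hochberg is available via a flag in `batch_rhythm`.
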