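# Methods

`msidiff` implements a discovery pipeline for tryptic-peptide MALDI mass
spectrometry imaging (MSI) of matched tissue pairs — one region sampled at
diagnosis and one at relapse for each patient — together with the
downstream validation statistics such a study uses (IHC quantitation,
survival analysis, responder ROC, drug-response correlation). This note
describes the model behind each stage, the defaults and their rationale,
what the synthetic-data generator does and does not emulate, and the
numerical choices that matter.

## Pipeline model

The analysis treats every tissue pixel as an observation. One profile
spectrum per pixel (m/z 800–4000) is preprocessed into a centroided peak
list; peak lists from all pixels, regions and patients are pooled and
clustered on the m/z axis into *peak groups*, each group standing for one
molecular species observed across the dataset. A group-by-pixel intensity
matrix then supports three statistics:

1. **Ranking** — per group, patient and region, the median over pixels of
   `ln(intensity + offset)`; the per-patient contrast is the relapse minus
   diagnosis median-log; groups are ranked by the absolute cross-patient
   median of those contrasts.
2. **Discrimination** — per group and patient, the ROC/AUC of relapse
   versus diagnosis pixel intensities with a two-sided Mann–Whitney test,
   Benjamini–Hochberg adjusted across groups within each patient. The AUC
   is computed by the midrank formula, so `auc = U/(n1·n2)` holds exactly
   and the AUC is the probability that a random relapse pixel outranks a
   random diagnosis pixel. Zero intensities are retained as scores —
   absence of a peak is informative.
3. **Identity transfer** — LC-MS/MS identifications of the same digests
   are deconvoluted to singly protonated m/z (`M = z·m/z − z·m_p`,
   `[M+H]+ = M + m_p`, proton mass 1.007276 Da) and matched to group
   centroids within ±0.25 Da, boundary inclusive. Matching is
   experimental-to-experimental: both coordinates carry the same residual
   calibration bias, which cancels, whereas theoretical sequence masses
   may not sit within tolerance. The theoretical monoisotopic `[M+H]+` is
   attached to every match as a QC delta.

A protein is called when at least `min_patients` (default 3) patients each
have at least one matched peak group passing the differential thresholds
(BH q ≤ 0.05 and oriented AUC ≥ 0.6) in one consistent direction; proteins
with support in both directions are reported as conflicts, not called.

## Preprocessing

Fixed order: Gaussian smoothing → TopHat baseline subtraction → SNR peak
picking → internal-calibrant recalibration → cross-spectrum normalization.
The stages are pure per-spectrum operations until normalization, so the
chain is trivially invariant to spectrum order.

**Smoothing.** Gaussian kernel, sd in Da converted to samples by the
median axis spacing. The default sd is 0.005 Da — deliberately below one
sample at the generator's 0.01 Da axis pitch. Heavier smoothing correlates
the noise over exactly the span the peak picker's width criterion counts,
which converts noise wiggles into peak-shaped bumps; with near-iid noise
the width criterion retains its rejection power. The parameter is exposed
for data whose noise is already correlated at acquisition.

**Baseline.** Morphological opening (erosion then dilation) with a flat
1.5 Da structuring element; the opened trace is the baseline. The opening
is idempotent, anti-extensive (baseline ≤ signal) and annihilates flat
signals; the element should be at least ~5× the peak FWHM so peaks are not
eaten into the baseline.

**Peak picking.** A local maximum is a peak when

* its apex height *above the local median floor* is ≥ `snr_threshold`
  (default 2) times the local robust noise level, and
* the contiguous region above half that height spans ≥ `min_peak_points`
  samples (default 7).

Noise and floor are estimated in 50 Da windows with 50% overlap and
interpolated to each apex. The floor matters because the opening leaves
the residual resting on its local *minimum*, not its mean — heights
measured from zero would carry a systematic ~2σ offset and an SNR-2
threshold would pass everywhere. The noise scale is the distance from the
window median to its 84.13th percentile: on Gaussian noise this equals one
sd (like 1.4826×MAD), but unlike the two-sided MAD it stays calibrated on
zero-inflated signals, where clipping at zero can place half of all
samples exactly at the median. The width criterion is what makes an SNR
threshold as low as 2 usable: single-sample noise excursions clear an
amplitude threshold constantly but almost never hold half their height
across seven consecutive samples, while a real 0.1 Da-FWHM peak sampled at
0.01 Da spans ~10. Centroids are floor-corrected intensity-weighted means
over the above-half region; the reported intensity is the floor-corrected
apex. When several local maxima share one above-half region (noise riding
a real apex), only the tallest is emitted.

**Recalibration.** Each spectrum's peak list is matched to the theoretical
masses of the sprayed standards (Angiotensin I, [Glu1]-Fibrinopeptide B, a
Dynorphin A fragment, ACTH 1–24; the Dynorphin fragment length is
lab-specific and the table is fully configurable) within ±0.5 Da, and a
least-squares affine map `mz_true ≈ a·mz_obs + b` is applied to all peaks.
Spectra with fewer than two matched calibrants are flagged and left
uncorrected rather than dropped. On exactly affine drift the fit is exact;
under centroid jitter the residual is the jitter scale divided by ~√n.

**Normalization.** Default `calibrant`: intensities divided by the
spectrum's mean matched-calibrant intensity, rescaled by the cohort-median
calibrant level so values keep their original magnitude (and the log
offset stays meaningful). The sprayed standards are applied uniformly, so
their per-pixel level measures detection efficiency alone. TIC
normalization is provided but not default: when a meaningful fraction of
the signal genuinely changes between conditions, TIC scaling transfers
that change to every other species (closure/compositional bias) — in the
default synthetic design it is strong enough to flip all background
species significantly "down in relapse". `none` is the identity.

## Peak grouping

Standard DBSCAN on the 1-D m/z coordinate of the pooled peak list:
ε = 0.02 Da (absolute, not ppm), a core point has ≥ 100 peaks (itself
included) within ±ε, clusters are maximal density-connected core sets plus
their border points, everything else is noise. The implementation sorts
once and uses binary-search neighborhoods; core components reduce in 1-D
to maximal runs of cores with consecutive gaps ≤ ε. Border points join the
cluster of their *nearest* core (ties to the lower m/z), which makes the
partition deterministic and invariant to input order — generic DBSCAN
implementations assign shared border points in discovery order. The test
suite checks the partition against an independent brute-force
density-reachability oracle built from the dense pairwise distance matrix.

Groups with fewer than 10,000 member peaks are discarded ("at least"
boundary inclusive). These pooled-count filters presume full-tissue pixel
counts; `PipelineConfig.desk_profile(n_pixels)` rescales them to the same
proportions at desk scale (`min_group_size = n_pixels/2`,
`min_density = 0.5% of n_pixels`, floors applied). Per-pixel group
intensity is the sum of the group's member-peak intensities in that pixel
(0 when absent). The group centroid is the intensity-weighted mean member
m/z.

## Downstream validation statistics

* **H-score** `= 100·(f1 + 2·f2 + 3·f3)` from intensity-bin cell
  fractions, bounded in [0, 300]; tissue value is the mean over its 5–6
  scored areas. Stromal markers use percent positive pixels. Paired
  diagnosis/relapse comparison is a two-sided paired t test, by default
  pairing individual areas within each patient (a per-tissue averaging
  mode is provided).
* **Kaplan–Meier** curves via the product-limit estimator (lifelines),
  with at-risk counts; without censoring the curve equals the empirical
  survivor function exactly.
* **Log-rank** with hypergeometric (tie-corrected) variance. The hazard
  ratio is the O/E form `HR = (O_A/E_A)/(O_B/E_B)` with
  `CI = exp(log HR ± 1.96·√(1/E_A + 1/E_B))` — a deliberate,
  dependency-free approximation to a Cox HR, documented as such.
* **Best cut-off**: all distinct marker values between the 10% and 90%
  quantiles with both arms ≥ 10% of n are scanned with a vectorized
  multi-cutoff log-rank; the cut-off minimizing the naive p is selected
  (subjects with marker ≥ cutoff form the high arm; ties take the smallest
  value). Because this scan is an optimization, the naive p is
  optimistically biased; a permutation-adjusted p (marker labels permuted,
  scan repeated, default 1,000 permutations) is always reported beside it.
  Markers measured by several probes are averaged per subject first.
* **Responder ROC** reuses the midrank AUC with non-responders as the
  positive class. **Drug-response correlation** offers Pearson (t
  reference) and Spearman; the Spearman p is exact by full permutation
  enumeration for n ≤ 9 without ties.

## Synthetic study design

The generator is the package's stand-in for the patient cohort and defines
the conditions every end-to-end guarantee is tested under:

* 4 patients × 2 regions (diagnosis/relapse), 20×20 pixels per region
  (3,200 spectra), m/z 800–4000 at 0.01 Da pitch.
* A 30-peptide tryptic panel. Five peptides are planted at fold change 3
  in relapse — the real marker peptides GPGDLEAPSNLVISER (COL12A1),
  IGGNEGIDVPIPR (FUBP1), VPLDEALQRGTVDAR (PLEC), VLLPLIFR (SLC4A1) and
  VLDPFTIKPLDR (TKT); 25 background peptides (fold 1, base abundances
  40–160) were generated once with pairwise `[M+H]+` separation > 1 Da
  from each other, the markers and the calibrants, and are shipped as
  frozen defaults.
* Per pixel: exponential baseline (amplitude 20, decay 600 Da), Gaussian
  peaks of 0.1 Da FWHM (a generic reflectron-TOF stand-in; no peak-shape
  model is prescribed by the workflow), four calibrant peaks (amplitude
  150), additive N(0, 1) noise clipped at zero.
* Intensity model: a shared log-normal per-pixel gain (CV 0.2, mean 1) —
  the detection-efficiency variation normalization exists to remove —
  times independent per-peak log-normal variation (CV 0.2, mean 1), times
  the region fold change; peaks drop out of a pixel with probability 0.05.
  Log-normal variation keeps intensities positive and makes median-log
  statistics natural.
* A global affine mass drift (slope 1+1e-5, offset +0.02 Da) applied to
  every peak center, recovered by recalibration.
* The LC-MS/MS table lists every panel peptide in both sample pools at
  charges 1–3 with zero measurement error by default (configurable ppm
  jitter), so identity transfer is limited only by the imaging centroids.
* IHC tables: per-area intensity-bin fractions are the exact
  Binomial(3, λ/3) probabilities at a latent stain level λ, so the area
  H-score is exactly 100·λ; relapse shifts λ by `effect`/100 with
  between-area Gaussian jitter. In the noiseless limit every paired
  difference equals `effect` exactly.
* Survival cohorts: exponential event times (baseline hazard 1/12 per
  month), hazard multiplied by the true HR for subjects at or above the
  marker median, independent exponential censoring tuned to the requested
  censored fraction.

What the generator does **not** emulate: isotope envelopes and
deisotoping, matrix cluster ions, spatial autocorrelation of tissue
texture (pixels are exchangeable within a region), chimeric/overlapping
peaks closer than 1 Da, search-engine score distributions or FDR, and
nonlinear (TOF-typical) mass error. Passing end-to-end tests therefore
demonstrate that the statistics recover what the intensity model plants at
desk scale — not that the pipeline is robust to those unmodelled features
of real acquisitions.

All generators are fully determined by a seed; the per-pixel draw order is
fixed, so identical seeds give identical datasets.

## Replicate-level calibration studies

Two guarantees are measured over replicates rather than single runs: the
null calibration of the discrimination stage (all folds 1: mean pixel AUC
in [0.45, 0.55]; BH q ≤ 0.05 in at most 7% of group-patient pairs) and the
survival statistics (O/E HR recovery at true HR 2, n = 500/arm; best
cut-off null with ≤ 7% adjusted p ≤ 0.05). The null-calibration replicates
draw group-by-pixel matrices directly from the intensity model
(`simulate_group_matrix`) rather than rendering and re-picking 200 × 3,200
profile spectra: downstream of grouping the two are the same experiment,
and the spectral path is already exercised end to end by the
planted-recovery run. Problem sizes used throughout: one full spectral run
of the default design; 200 matrix replicates for the null; 200 cohorts of
1,000 subjects for HR recovery; 200 cohorts of 60 subjects × 200
permutations for the best-cutoff null.

## Numerical choices and degenerate inputs

* Exact Mann–Whitney p by enumeration for pooled n ≤ 12 without ties;
  otherwise normal approximation with tie and continuity corrections. Two
  identical constant samples return U = n1·n2/2, p = 1 with a warning.
* Natural log with offset 1 for ranking; the base rescales contrasts and
  can never reorder ranks.
* Ranking ties (equal |summary contrast|) break by centroid m/z ascending;
  best-cutoff ties take the smallest cutoff; border-point ties in DBSCAN
  take the lower-m/z core.
* All-zero spectra yield empty peak lists (not an error); zero-TIC or
  calibrant-free spectra are flagged and excluded from normalization, not
  silently dropped.
* Tables are serialized with 12 significant digits (round trip < 1e-9
  relative); NaN round-trips as an empty field.
* Identical config + seed reproduce result tables byte-for-byte.

## Known limitations

* The O/E hazard ratio is biased toward the null relative to a Cox
  estimate when arms are very unbalanced or the HR is far from 1; its CI
  is the standard approximation.
* The peak picker's width criterion assumes the peak FWHM spans several
  samples (≥ ~7 at default settings); undersampled acquisitions need
  `min_peak_points` lowered accordingly, which weakens noise rejection at
  SNR 2.
* Group intensity is the sum of member-peak apexes, one convention among
  several (apex vs area; the choice only rescales group intensities when
  peak shape is constant).
* Identity transfer reports all candidates within tolerance;
  disambiguation of multi-matches is left to the caller (rank-annotated),
  since no principled rule exists at ±0.25 Da without MS/MS evidence.
* The permutation adjustment in `best_cutoff` controls the selection
  optimism of the cutoff scan, not confounding or cohort heterogeneity.
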