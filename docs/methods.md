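# Methods

This note documents the models, parameter choices and numerical decisions
behind each stage of the pipeline, what the synthetic data generator does
and does not emulate, and the known limitations.

## Synthetic imaging data

The generator produces a continuous-mode imaging dataset: one common
profile m/z axis and one intensity vector per pixel, organized as
patients → ROIs (classes WD, PD, optionally control) → pixels. Each
spectrum is the sum of three parts.

**Baseline noise.** Additive i.i.d. exponential noise with scale
`baseline_scale` (default 1, arbitrary units). An exponential was chosen
because it is nonnegative (so spectra satisfy the intensity ≥ 0 contract
without clipping) and has a heavy enough tail to produce realistic
spurious peaks above any threshold. The baseline scale is the unit in
which planted-peak S/N is expressed. This is a stand-in, not a claim
about FT-ICR noise physics.

**Peptide signals.** Each of `n_peptides` planted peptides (drawn from a
tryptic-digest table) contributes a charge-1 isotope envelope: Gaussian
peaks (σ = `peak_sigma_mz`, default 0.006 Da) at M, M + 1.00335 and
M + 2·1.00335 with relative abundances λᵏ/k!, λ = 0.000594·M — a
truncated-Poisson approximation to an averagine isotope distribution that
is analytically checkable (the integral of each member over ±0.02 m/z
recovers its assigned area exactly when 0.02 ≥ 2.6σ). Per-peptide base
abundance is log-uniform over one decade starting at
`snr_of_planted_peaks` (default 15) times the baseline unit. Per pixel
and per peptide, intensity is multiplied by log-normal noise with
log-scale σ = `noise_sd` (default 0.3). Differential peptides are
additionally multiplied by `fold_change` in PD pixels.

**Mass drift.** Each spectrum carries one rigid multiplicative shift,
uniform in ±`drift_max_ppm` (default 30 ppm) — exactly the error model a
global ppm alignment can correct.

Planted peptides are selected so that no isotope slot of one envelope
comes within 0.3 Da of a slot of another. The guard exceeds the default
binning window (12 scans), so tolerance binning can never merge two
planted envelopes into a hybrid feature; ground truth therefore stays
identifiable feature-by-feature. Real spectra do contain overlapping
envelopes; resolving them is explicitly out of scope for the charge-1
deisotoper, so the generator does not produce them.

Not emulated: spatial autocorrelation beyond ROI membership, matrix
cluster/adduct ions, multiply charged species, chemical baseline drift,
detector saturation. Passing tests on this generator therefore shows the
statistical machinery is correct under the assumed error model — not that
the pipeline is robust to every artifact of real acquisitions.

## Preprocessing

Stage order is align → RMS-normalize → peak-pick → bin → prevalence
filter.

*Alignment* models miscalibration as a single multiplicative ppm shift
per spectrum, which is a translation on a log-m/z axis. Spectra are
cross-correlated against the mean of the currently shifted spectra on a
uniform log-m/z grid upsampled 2x, over integer lags covering ±50 ppm;
the apex lag is refined by 3-point parabolic interpolation and the
procedure is iterated 3 times with the reference recomputed. For
efficiency the correlation is evaluated only on signal-bearing grid
columns (mean spectrum above median + 7 robust sigma, dilated by the
search width; fallback to the top decile, then to the full grid — the
restriction changes nothing when spectra are dense). Applied shifts are
clipped at the 50 ppm bound. Alignment recovers *relative* shifts; a
common offset of the whole dataset is unobservable. On the default
synthetic conditions the post-alignment drift residual is well under
1 ppm (95th percentile ≈ 0.04–0.3 ppm).

*Normalization* divides each spectrum by its root mean square.

*Noise estimation* (needed to realize "S/N = 7") is 1.4826 × the median
absolute deviation of the lower 90% of intensity order statistics —
robust to the sparse tall peaks that sit on the baseline. A zero estimate
(noise-free input) disables the threshold rather than dividing by zero.

*Peak picking* keeps local maxima with height ≥ 7 × the noise estimate
and refines each apex with a 3-point parabolic fit (plain parabola, not
log-parabola: more robust at low S/N, and its residual centroid bias is
absorbed by the binning tolerance).

*Binning* pools all centroids, sorts them, and merges left to right: a
centroid joins the open bin while it is within 12 scans × the median axis
spacing of the bin's running intensity-weighted consensus mass. "Scan"
means one profile data point. Matrix entries are picked peak heights
(maximum if one spectrum contributes several peaks to a bin); absences
stay 0 and are never imputed.

*Prevalence filter* removes features present in fewer than 5% of spectra
("fewer than" is strict, so exactly 5% survives). With 2000 spectra this
filter removes essentially all baseline-noise features, whose prevalence
concentrates around 2–3%.

## Deisotoping

Greedy left-to-right over the ascending feature masses: a feature seeds
an envelope; for each expected slot (+1.00335, +2.00670 Da, tolerance
0.02 Da) every unassigned feature in the window whose mean intensity is
at most 1.2 × the previous slot's is absorbed (near-duplicate features
inside one window are all absorbed; the closest one represents the slot).
Envelopes stop at 3 members or at the first empty slot. Only the
monoisotopic member is kept; isotope intensities are discarded, not
summed, because the downstream unit is the monoisotopic mass, not
envelope abundance. The 1.2 declining factor is loose on purpose: below
~1800 Da the monoisotopic peak is the base peak, and at 2000 Da the
expected M+1/M ratio reaches ≈ 1.19, so 1.2 still accepts true envelopes
while rejecting most coincidental neighbors. The reduction is idempotent.

## Differential screen

The screen deliberately uses two different units. The replicated ROC
stage works on spectrum-level intensities: per replicate, an equal number
of spectra per class is drawn with equal per-patient quotas
(`n_per_condition // n_patients` each, without replacement; quotas shrink
with a warning if a patient cannot fill them), and the per-feature AUC is
the Mann–Whitney U statistic scaled to [0, 1] with ties counted ½,
oriented PD over WD. A feature is a candidate when
max(AUC, 1 − AUC) ≥ 0.70 in at least 3 of 5 replicates — the complement
folds in features that are *lower* in PD, which the screen must catch
since most discriminative signals go that way. Five replicates are read
as five independent re-draws (seeded seed, seed+1, …); a
leave-one-patient-in mode (`replicate_mode="per-patient"`) is provided
for comparison.

The confirmation stage works on ROI means: one mean intensity per ROI
per feature, two-sided Mann–Whitney between WD and PD ROIs — exact by
full enumeration when both groups have ≤ 8 ROIs, otherwise the normal
approximation with tie and continuity corrections — followed by
Benjamini–Hochberg over the candidate set (a flag widens BH to all
features). Significance requires the candidate rule and p ≤ 0.05 and
q ≤ 0.05; direction is the sign of (PD − WD) median ROI mean.

One subtlety the synthetic data exposes: RMS normalization couples
features. When 5% of peptides double in PD, every other feature's
normalized intensity drops by a few percent in PD, and with 50-pixel ROI
means that shift alone would reach nominal significance. The
spectrum-level ROC gate (AUC ≥ 0.70 against per-pixel noise) is what
keeps such globally-coupled null features out of the tested set; in the
null and planted-effect evaluations the realized false-positive rate is
at or near zero.

## Identity assignment

The tryptic digest cleaves after K or R except before P, emits all
products with up to `max_missed_cleavages` (default 1, typical for
in-situ tryptic digests) missed sites, and enumerates variable
modifications (oxidation-M +15.99491, formaldehyde-K +12.000) up to 2 per
peptide; carbamidomethyl-C (+57.02146) is applied to every cysteine.
Monoisotopic [M+H]+ = Σ residue masses + 18.010565 + 1.007276, from a
standard monoisotopic residue table kept in source. The ppm window uses
the theoretical mass in the denominator:
(observed − theoretical)/theoretical × 10⁶, accepted when |ppm| ≤ 10.
Match status is `unique` (one protein), `family_multi` (several proteins
all mapped to one family by a user-supplied protein→family table; kept),
`ambiguous`, or `unmatched`; all candidates are reported sorted by |ppm|,
and no winner is chosen silently. LC-MS/MS identification tables are
filtered at score ≥ 25 and FDR ≤ 0.01 (both boundaries inclusive per
their "≥"/"≤" definitions), with masses recomputed from sequence and
checked against any declared mass column at 5 ppm.

## Enrichment

One-sided (greater) Fisher's exact test per term on the 2×2 table of
query × term membership over the background; the one-sided form matches
the overrepresentation question (a two-sided flag exists). The background
defaults to the union of the annotation's gene sets; an explicit
background list reproduces a genome-wide reference. Terms with zero query
overlap are skipped before BH, as overrepresentation tools
conventionally do (a flag includes them). Fold
enrichment is stored exactly; only display formatting renders values
above 100 as ">100".

## Survival

The Kaplan–Meier estimator, log-rank test and hazard ratio are computed
from one shared O/E/V tabulation over pooled distinct event times
(hypergeometric variance, tie-aware); the log-rank χ² matches
`lifelines.statistics.logrank_test` to machine precision on random
cohorts with ties. HR = (O_hi/E_hi)/(O_lo/E_lo) with
CI = exp(log HR ± 1.96·√(1/E_lo + 1/E_hi)). This O/E form is
self-contained and consistent with the log-rank machinery but is known to
shrink toward 1 relative to a Cox estimate at large effects (≈ 2.3–2.4
at a true HR of 3); it approximates, and does not equal, a Cox fit.

The best-cutoff scan enumerates midpoints between consecutive distinct
expression values strictly inside [Q1, Q3], computes the log-rank test at
each, and keeps the minimum-p cutoff (equivalently maximum χ² at 1 df;
both metric names are accepted). Patients with expression equal to the
cutoff fall in the low arm. No multiplicity correction is applied across
scanned cutoffs — mirroring common online survival tools — so the
reported minimum p is optimistic by construction; the full scan is
returned so that optimism is inspectable.

The synthetic cohort plants a hidden threshold: expression is bimodal
(uniform on (0, 0.45) and (0.55, 1), leaving an empty gap around 0.5),
event times are exponential with the hazard multiplied by `true_hr` above
the threshold, and censoring is an independent exponential whose rate is
matched to the cohort mixture so that roughly the requested fraction is
censored. A property worth knowing: the argmax of the log-rank statistic
over rank-adjacent cutoffs wanders a few patients around the true change
point (per-patient drift is small relative to per-patient noise), so the
scan localizes the threshold to within a handful of rank positions
(median ≈ 2, ≥ 95% within 10 at HR 3, n 200) but lands exactly inside
the empty gap only in roughly a quarter of cohorts — at HR 3 this
fraction is an intrinsic property of min-p cutoff selection, not an
implementation artifact, and it improves only slowly with effect size.

## Problem sizes and numerical choices

The evaluation-scale synthetic study uses 5 patients × 2 classes × 4
ROIs × 50 pixels (2000 spectra), 300 peptides (15 differential at fold
2.0), drift ≤ 30 ppm, m/z 600–2000 at 0.02 Da spacing with peak
σ = 0.012 Da, and a per-condition ROC sample of 500 — a scaled axis and
sample size that preserve the full structure of the problem while keeping
a complete run near twenty seconds. The generator's instrument-range
bound (600–3500 Da) and all processing defaults (50 ppm / 3 iterations /
oversampling 2, S/N 7, 12 scans, 5% prevalence, 0.02 Da isotope
tolerance, AUC 0.70 in 3/5, n = 3000 per condition at cohort scale,
α = FDR = 0.05, ±10 ppm) are the published processing values and are all
configurable.

Floating point: intensity blocks are float32 (memory), statistics are
accumulated in float64. Parabolic refinements clip the interpolated
offset to half a sample. All randomness flows through
`numpy.random.default_rng` seeds carried in the configuration; pipeline
outputs are byte-identical across reruns with the same seed.

## Limitations

- Charge 1+ only; no envelope deconvolution or overlap resolution.
- No baseline subtraction and no normalization alternatives to RMS.
- Mass matching is single-stage accurate-mass only; no MS/MS scoring and
  no decoy-based FDR for the matching step.
- The O/E hazard ratio is not a Cox estimate (see above).
- The synthetic generator's noise model is a documented stand-in; results
  on it bound what can be claimed about real FT-ICR data.
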