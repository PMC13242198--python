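# Methods

This note documents the models behind `tacsattn`, the parameters that
matter, the numerical choices made where conventions differ, and what the
synthetic-data generator does and does not emulate.

## Task model

One session is a 120-trial Posner cueing task. Trials are stratified
exactly: 30 per (cue type × CTI) cell with cue type ∈ {endogenous,
exogenous} and cue–target interval (CTI) T ∈ {0.5, 1.0} s, and 24 valid /
6 invalid trials within each cell. The 80/20 validity split is realized as
an exact count rather than a Bernoulli draw; the published proportions are
stated as probabilities, but exact stratification makes every count
assertion deterministic and matches the session totals. Per-class trial
durations are fixed constants — (endo, 0.5) → 4.55 s, (endo, 1.0) → 5.05 s,
(exo, 0.5) → 3.682 s, (exo, 1.0) → 4.182 s — so a default session lasts
523.92 s. Cue sides are drawn 50/50 per trial and the target side follows
from validity. Pre-CTI fixation/cue timing is treated as opaque: epochs
are aligned only to cue onset (CTI segments) or target onset (ERP
segments), since only the per-class totals are specified.

## Reaction-time model

Reaction times are truncated-at-zero normal per trial type, parameterized
by a pre-session mean/SD per type (defaults: Endo-Valid 334.4 ± 65.9 ms,
Endo-Invalid 425.4 ± 110.0, Exo-Valid 355.5 ± 88.2, Exo-Invalid
373.0 ± 79.7 — the across-group averages of the published pre-session
cells). Post sessions add a trial-type-specific practice shift (both
groups; defaults −5.2 to −12.2 ms, the sham pre→post changes) and, for the
active group only, a stimulation after-effect (defaults −17.7 / −23.9 /
−35.9 / +6.0 ms — the active-minus-sham change differences, with the
characteristic null effect on Exo-Invalid trials). Lapses (default 1%)
yield missing responses; fast guesses (default 2%) are uniform on
[0, 100) ms and therefore always fall to the response-window filter. A
normal family is the minimal choice consistent with reported means/SDs and
non-rejected normality screens; no subject-level random intercept is
modeled, so trials within a subject are i.i.d. — adequate for interaction
inference (intercepts cancel in change scores) but optimistic for
between-group main effects on raw levels.

RT cleaning retains the closed interval [0.1, 1.0] s (the exclusion rules
are strict inequalities, < 100 ms and > 1 s). "Correct response" is
operationalized as any keypress inside the retention window — the task has
a single response key and no other correctness criterion. All inference is
subject-as-unit: trials are averaged to one value per subject × session ×
trial type before any test, consistent with F-test denominators of df 16
at n = 9 per group.

## EEG generator

Each trial yields a cue-aligned CTI segment (T samples × rate) and a
target-locked segment (−0.1 to 0.5 s). Every channel of every segment is
the sum of three independent processes plus, for target segments, the
component templates:

* **Scale-free background** — spectral synthesis: Fourier coefficients
  with power ∝ f^−(2α−1) and Gaussian random amplitudes/phases, rescaled
  to the exact target variance (default 10 µV², α = 0.8). The expected DFA
  exponent over the fit range equals the target α for α ∈ (0, 2).
* **Band-limited alpha and gamma** — white noise spectrally masked to
  8–12 Hz (default 5 µV²) and 30–45 Hz (default 1 µV²), rescaled to exact
  band variance.
* **N1/P3 templates** — Gaussian windows amp·exp(−(t−λ)²/2w²); defaults
  N1 = −3 µV at 140 ms (w = 25 ms), P3 = +4 µV at 320 ms (w = 50 ms).

Active-group post-session epochs apply a multiplicative/additive effect
specification (defaults: alpha power × 0.7, gamma power × 1.4, background
exponent − 0.1, N1 amplitude × 1.3, P3 amplitude × 1.25, P3 latency
− 15 ms), emulating the direction of the published after-effects. Effects
are applied uniformly across channels and trial types; real data showed
trial-type-specific ERP effects and spatially clustered power/LRTC
effects, so passing recovery tests demonstrates estimator correctness, not
spatial selectivity. No ocular/muscle artifacts are simulated (the manual
ICA screening step of real pipelines has no synthetic counterpart), no
continuous raw EEG is produced, and channels are spatially independent —
synthetic topographies carry no volume-conduction correlation.

The default sampling rate is 256 Hz to keep desk-scale simulation cheap;
all operations are rate-agnostic and rates up to the hardware-typical
1,200 Hz are supported. The channel set is a standard 32-label 10–20
montage containing every electrode the analyses reference; electrode
adjacency connects pairs closer than 1.3 × the median nearest-neighbor
distance of the 2-D layout (55 edges, connected), and is shipped as a
reviewable TSV so users may substitute their own.

## ERP quantification

Preprocessing order is fixed as common-average reference → zero-phase
low-pass → per-channel linear detrend; all steps are linear so the order
only pins down bit-stable outputs. The filter is a windowed-sinc (Hamming)
FIR with 30 Hz cutoff, 7.5 Hz transition band, and ≥ 53 dB single-pass
stopband attenuation, applied forward-backward; only the cutoff is an
external constraint, the realization is this package's choice. Note that
linearly detrending a finite sinusoid itself shifts peak amplitude by a
few percent (the regression slope of a sine over a finite window is
nonzero), so filter-response guarantees are stated for the filter stage,
not the whole chain.

ERPs average trials, then ROI channels, then subtract the −0.1–0 s
baseline mean. Component windows are closed intervals with half-sample
grid tolerance: N1 90–200 ms (negative), P3 250–400 ms (positive). Mean
amplitude is the arithmetic sample mean in the window. Fractional-area
latency rectifies the waveform (absolute value — polarity labels the
component but does not enter the area), accumulates trapezoidal area, and
returns the linearly interpolated time at the requested fraction (default
0.5; 0.25/0.75 supported for sensitivity checks). Time-resolved pre/post
contrasts are per-timepoint paired t-tests with Benjamini–Hochberg
adjustment across timepoints.

## Multitaper band power

CTI segments are mean-subtracted and tapered with DPSS windows at full
analysis bandwidth 8/T, i.e. NW = T·(8/T)/2 = 4 for either CTI length, so
the admissible taper count is invariant: of the 2·NW = 8 candidates, the
seven with spectral concentration λ > 0.9 are retained and averaged with
flat weights (eigenvalue weighting is indistinguishable at λ > 0.9 and
flat averaging matches the concentration-cutoff semantics). PSDs are
one-sided densities in µV²/Hz; band power is the closed-interval
trapezoidal integral, so alpha on a 0.5 s segment uses the three resolved
bins {8, 10, 12} Hz.

Interpretation caveat: the estimator's spectral window is ±4/T Hz wide, so
the estimate is the true spectrum smoothed over that window. Total power
obeys Parseval (within ~2% at typical segment lengths after mean
subtraction), but a narrowband process leaks part of its power outside its
nominal band — about 47% of an 8–12 Hz process at T = 1 s and more at
T = 0.5 s. `band_capture_fraction` computes the expected in-band fraction
from the taper spectra; absolute band powers should be compared against
generator parameters through it, whereas pre/post ratios are unaffected
because the factor cancels. Per-CTI-length band powers are computed and
then averaged across trials (whether the original analysis pooled spectra
before or after integration is unspecified; averaging band powers is the
simpler convention and is what the pipeline does).

## Detrended fluctuation analysis

The series is mean-subtracted and cumulatively summed; for each window
size n the profile is partitioned into ⌊N/n⌋ contiguous non-overlapping
segments from the start, a least-squares line is removed per segment, and
F(n) is the RMS residual over the covered samples (the trailing remainder
is excluded and the normalization adjusted accordingly; a single forward
pass, no reversed-pass averaging). α is the OLS slope of log F(n) vs
log n over ~15 log-spaced integer window sizes in [25, 200] — the fit
range is externally fixed, the grid density is this package's choice.
Preconditions: N ≥ 2·max(n) and non-zero variance.

Because 0.5 s CTI epochs at 256 Hz (128 samples) cannot support n = 200,
the pipeline concatenates all same-condition CTI segments of a
subject-session (each mean-subtracted) before a single DFA; a per-epoch
mode (DFA per trial, exponents averaged) is provided for high-rate data
where individual epochs are long enough. Concatenation introduces segment
boundaries, which mildly perturbs the largest windows; the generator
round-trip bounds this bias at ≲ 0.1 in α under default settings.

## Statistics

**Mixed ANOVA.** Classical univariate sums of squares for one
between-subject factor (group) and one or two within-subject factors, on a
balanced complete table with one observation per subject per cell. The
between factor is tested against subjects-within-groups; each within
effect and its group interaction against the corresponding
factor × subject-within-group term. Partial η² =
SS_effect/(SS_effect + SS_error-for-that-effect). No sphericity correction
is applied — matching integer published dfs. (Several published partial η²
values are internally inconsistent with their own F and df; this
implementation keeps the standard definition and does not attempt to
reproduce those specific values.) No stock Python routine covers the
two-within/one-between case, so the decomposition is implemented here and
verified against an independent brute-force cell-mean oracle and, for the
one-within case, against `pingouin.mixed_anova`.

**Multiplicity.** Bonferroni (single-step), Holm (step-down), and
Benjamini–Hochberg (step-up) adjustments with clipping at 1 and enforced
monotonicity; the family size may exceed the number of observed p-values.

**Cluster-based permutation.** Per-electrode t-tests (paired or
independent); electrodes with |t| above the two-sided critical value at
p < .05 are partitioned into same-sign connected components of the
adjacency graph; components of ≥ 2 electrodes are clusters with mass Σt.
The null is the maximum absolute cluster mass over 2,000 random
relabelings — sign-flips within subject for pre/post contrasts,
group-label shuffles for between-group contrasts (the exchangeability
scheme per contrast is this package's choice) — and
p = (1 + #{null ≥ observed})/(n_perm + 1), a ≥-comparison with the +1
convention so p is never zero and ties count conservatively.

**McNemar.** Continuity-corrected: χ² = (max(|b−c|−1, 0))²/(b+c) on the
discordant cells, χ²₁ reference. The corrected form is used because it
uniquely reproduces the published blinding statistic (χ² = 1.125 from
discordant cells 2 and 6); it is floored at zero when |b−c| ≤ 1.

**Sensitivity.** Minimum detectable Cohen's d for a two-sample t-test
(applied to pre–post change scores compared between groups): the
noncentral-t power equation is solved for d by bisection to 1e−6. The
multiplicity-adjusted follow-up alpha is taken as 0.05/4 = 0.0125
(single-step, conservative relative to a stepwise scheme).

## Pipeline and reproducibility

A run is a single JSON document (seed, group size, schedule, RT model, EEG
specification, stage toggles, output directory). The top-level seed fans
out through CRC-tagged `SeedSequence` sub-streams per (stage, subject,
session), so stages are independently reproducible and a re-run is
byte-identical. Stages persist all artifacts (CSV/TSV/JSON; epochs as
HDF5 float32 with JSON provenance sidecars) and later stages read only
persisted artifacts, making runs re-entrant; the final report carries
SHA-256 checksums of every output.

## Problem sizes used in validation

The test suite validates at desk scale, chosen to make Monte Carlo
assertions stable: DFA recovery uses 60–200 replicates of 8,000–10,000
samples; Parseval uses 500 one-second segments; cluster error rates use
300 null and 200 planted-effect experiments at 200 permutations each
(the pipeline default remains 2,000); the end-to-end behavioral check uses
200 replicates of a full 18-subject, 120-trial-per-session experiment
with a planted 25 ms active-group reduction at 60 ms trial SD. Seeds are
fixed throughout; tolerances are 3-SE-style bands around the generator's
ground truth.

## Known limitations

* Channels are statistically independent in the generator: no spatial
  covariance, no volume conduction, no topographic structure of effects.
* The RT model lacks subject-level random effects and right-skew
  (ex-Gaussian) structure typical of empirical RT distributions.
* Absolute multitaper band powers are biased low for narrowband processes
  (see above); comparisons across conditions are unaffected.
* The ANOVA assumes balanced complete data and equal group sizes; there is
  no sphericity correction and no mixed-effects alternative.
* Cluster inference controls familywise error at the cluster level; it
  does not license electrode-level localization claims.
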