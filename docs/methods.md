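# Methods

## Problem and overall procedure

Saline–alkali-tolerant rice varieties accumulate starch (amylum) in the grain
more effectively than sensitive varieties, and that difference is visible in
the grain's Raman spectrum. The pipeline turns a set of labelled grain
spectra into a binary tolerant/sensitive discriminant in five stages:

1. **Baseline difference.** Each raw trace x is smoothed with a zero-phase
   (forward–backward) low-pass IIR filter into y, and the analysis proceeds
   on the difference X = x − y. The broad fluorescence background survives
   the heavy smoothing and is removed by the subtraction; the narrow Raman
   crests are largely rejected by the filter and therefore retained in X.
   Because the filter is applied forward and backward, its phase response
   cancels and crest positions are not shifted — a single causal pass would
   displace every apex toward higher shifts.
2. **Crest descriptors.** On X, all strict local maxima with topographic
   prominence above a floor are detected. Each of seven reference crests
   (480, 865, 941, 1129, 1339, 1461, 2910 cm⁻¹ — starch, amylopectin and
   sugar bands) is matched to the most prominent detected peak within a
   tolerance window, and described by four numbers: prominence, width at an
   evaluation line a fraction of the prominence below the apex,
   width_height (the apex-to-line distance), and peak_dif (the signed apex
   offset from the reference shift). A sample therefore contributes
   7 × 4 = 28 features; with sample name, label and number the table is
   N × 31.
3. **Feature selection.** Three reductions of the 28 columns: SKB keeps the
   K columns with the highest plug-in mutual information (bits, base-2 log,
   equal-frequency bins) against the label; RFE repeatedly removes the
   lowest-importance column of a random forest, scores every intermediate
   subset by stratified cross-validated accuracy, and returns the best
   subset (ties to the smaller one); SFM keeps columns whose single-fit
   forest importance reaches the mean importance.
4. **Classification.** Two models per feature set: a logistic regression
   (sigmoid of a linear score, decision threshold 0.5 with the boundary
   mapped to class 1) fitted by IRLS on standardised features with a tiny L2
   ridge; and a random forest of CART trees grown on bootstrap resamples,
   splits chosen by exhaustive Gini-index minimisation over midpoint
   thresholds, prediction by majority vote with ties to the lower label.
   Evaluation uses a stratified split with a global-floor 7:3 rule —
   train = ⌊0.7·N⌋ (156 → 109/47), per-stratum counts by largest remainder —
   selectors fitted on training rows only to avoid leakage (a flag restores
   whole-table selection).
5. **Attribution.** Covered crests map to constituents (480/2910 → amylum,
   865 → amylopectin + sugar ring, 941 → amylopectin, 1129/1339/1461 →
   sugar); substances are ranked by the count of selected descriptors on
   their crests. "Which constituent drives the discrimination" is
   operationalised as the top of that ranking.

## Synthetic data: what it emulates and what it does not

No public deposit of the original 156 grain spectra exists, so the package
generates spectra with the structure the analysis assumes: an
equally-spaced 200–3400 cm⁻¹ grid at 1.4 cm⁻¹ (2,286 points), Gaussian
lines of 25 cm⁻¹ FWHM at the seven reference shifts (a pseudo-Voigt mixing
parameter is available), a quadratic fluorescence background an order of
magnitude above the line amplitudes, i.i.d. Gaussian detector noise
(sd 5 intensity units against line amplitudes of 45–156), and per-sample
amplitude jitter of 10 % (CV). Four varieties, 39 grains each, labels
1/1/0/0, give the 156-sample design; the two tolerant-like profiles carry
+30 %/+25 % amplitude on the two amylum crests (480, 2910 cm⁻¹), encoding
the starch-accumulation difference. A two-variety variant confines the
class signal entirely to the amylum crests for parameter-recovery checks.

The generator does **not** emulate: correlated (pink/shot) noise, cosmic-ray
spikes, wavenumber miscalibration or instrument drift, line-shape asymmetry,
overlapping bands, or between-grain background variation. Passing tests
therefore demonstrate that the pipeline's machinery is correct and that it
recovers a planted amylum signal under realistic noise — not that the
specific published accuracies on the real grains are reproduced; those
depend on the unavailable spectra.

All randomness flows through one seeded `numpy.random.Generator` per
dataset; identical configurations are bit-identical.

## Parameters that matter

| parameter | default | why |
|---|---|---|
| filter family / order / cutoff | Butterworth, 3, 0.05 (of Nyquist) | smooth enough that y tracks the background but not 25 cm⁻¹ lines (at 1.4 cm⁻¹ sampling, the −3 dB point sits near a 56 cm⁻¹ period) |
| zero-phase edge handling | odd reflection padding, 3·(order+1) samples | standard practice; keeps edge transients out of the 200–400 cm⁻¹ region |
| min_prominence | 10 intensity units (2 × noise sd) | detects every real crest; spurious noise peaks are eliminated by prominence-ranked matching |
| rel_height | 0.5 | conventional width at half prominence |
| width_height convention | apex-to-line distance | the geometric reading of the descriptor; a switch yields the absolute line height |
| match tolerance | ±30 cm⁻¹ | generous against apex jitter, narrower than inter-crest spacing |
| SKB K / MI bins | 10 / 8 equal-frequency | K follows the protocol; 8 bins balances resolution against 156-sample bin counts. Features with ≤ 8 distinct values are binned by value so discrete columns are never collapsed |
| RFE | 1 column per iteration, 5-fold stratified CV | finest elimination granularity; stratification keeps both classes in every fold |
| SFM threshold | mean importance | the common convention; configurable |
| forest | 100 trees, ⌈√d⌉ features/split, unlimited depth, min split 2 | standard small-sample forest defaults |
| logistic fit | IRLS, L2 = 1e−4, tol 1e−6, ≤ 500 iterations | the ridge keeps separable fits finite without materially biasing coefficients |
| split | 0.7 global floor, stratified, largest remainder | a strict per-variety 7:3 cannot produce integer counts for 39-grain classes; the global-floor rule yields exactly 109/47 |

## Numerical choices and tie-breaking

- Prominence interval bases take the minimum closest to the apex when values
  tie; width crossings are linearly interpolated in index space and mapped
  through the (possibly non-uniform) shift grid, so widths are in cm⁻¹ and
  resolution-independent.
- X + y reconstructs x exactly as the defining subtraction; sums of the
  decomposition agree with x to floating-point rounding.
- Score/importance ties in selection break by lexicographic column name;
  split-candidate ties in CART break toward the lower feature index, then
  lower threshold; vote and leaf-majority ties break toward the lower class
  label; a logistic probability of exactly 0.5 maps to class 1. All are
  documented conventions chosen for determinism.
- Unmatched reference crests carry an all-zero sentinel plus a flag, keeping
  the table rectangular.
- Mutual information uses the convention 0·log 0 = 0 and clips negative
  rounding residue at 0.

## Problem sizes

The test-suite and reproduction runs use the full 156-sample design for
everything except the forest inside RFE's cross-validation loop, which uses
50 trees (28 subset sizes × 6 forest fits each makes it the dominant cost;
at 156 samples the subset ranking is stable well below 100 trees). The
final accuracy grid always uses the 100-tree default. Oracle comparisons
run on 1,000 random 30-point traces (peak geometry), 50-point signals
(filtering), and 12-row tables (CART splits).

## Known limitations

- Binary labels only; the four varieties enter solely through their
  amplitude profiles, not as a 4-class target.
- The CART split scorer is specialised to two classes (the forest refuses
  multiclass labels rather than silently mis-scoring).
- No deconvolution of overlapping lines and no curve fitting of peak
  shapes; descriptors are measured directly on the difference trace.
- The reduction of the ~18 visually significant crests to the seven
  reference shifts is literature-based, so the seven shifts are constants
  here, not a computed reduction.
- Only the zero-phase-difference baseline method is provided; wavelet or
  asymmetric-least-squares baselines are out of scope.
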