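# raman-rice

Raman-spectral chemometrics for identifying saline–alkali-tolerant rice
varieties. Screening rice for saline–alkali tolerance normally takes a
season of field trials; because tolerant varieties accumulate grain starch
(amylum) more effectively, the difference is visible in a grain's Raman
spectrum within seconds. This package implements the complete spectral
identification pipeline for breeders and spectroscopists: baseline removal
by a zero-phase-filter difference, crest shape-feature extraction, three
feature-selection strategies, two discriminant models, and a biochemical
attribution of the discriminating bands.

## Method

For a raw trace *x* on the 200–3400 cm⁻¹ grid, a third-order Butterworth
low-pass filter applied forward and backward (zero phase) gives a smoothed
trace *y*, and the analysis works on the difference

> X = x − y,

which removes the broad fluorescence background without shifting crest
positions. On X, seven reference crests (480, 865, 941, 1129, 1339, 1461,
2910 cm⁻¹) are each described by four shape features — topographic
prominence, width at half prominence, width_height, and peak_dif (apex
offset from the reference shift) — giving a per-sample feature vector of
7 × 4 = 28 numbers plus 3 metadata columns.

The 28 columns are reduced three ways: **SKB** keeps the 10 columns with the
highest mutual information I(X;Y) = Σ_x Σ_y p(x,y)·log₂ p(x,y)/(p(x)p(y))
against the tolerance label; **RFE** recursively drops the least important
column of a random forest and keeps the subset with the best cross-validated
accuracy; **SFM** keeps columns whose forest importance exceeds the mean.
Each feature set feeds a logistic regression g(z) = 1/(1+e^(−z)) over
h(w) = w·x + b (threshold 0.5) and a random forest of CART trees grown by
Gini-index minimisation, Gini(D) = 1 − Σ_k p_k², evaluated on a stratified
7:3 split. Finally each selected crest is attributed to its grain
constituent (amylum, amylopectin, sugar, sugar ring) and substances are
ranked by selected-descriptor count.

The study's original 156 grain spectra are not publicly deposited, so a
first-class synthetic generator emulates their structure (four varieties ×
39 grains, Gaussian lines on a fluorescence background with detector noise,
tolerant varieties boosted on the amylum bands); see `docs/methods.md` for
what the generator does and does not emulate.

## Worked example

Run the numbered analysis drivers from the repository root (each accepts
`--seed`):

```sh
python analysis/01_simulate.py --seed 1         # 156 PRN spectra + manifest
python analysis/02_extract_features.py --seed 1 # N x 31 feature table
python analysis/03_select_features.py --seed 1  # SKB / RFE / SFM matrices
python analysis/04_classify.py --seed 1         # selector x model grid
python analysis/05_attribute.py --seed 1        # constituent attribution
```

With seed 1 this prints:

```
feature table: 156 rows x 31 columns -> results/feature_table.csv
all seven crests matched in 156/156 samples
Initial: 28/28 features (100.0%), crest coverage 100.0%
SKB    : 10/28 features (35.71%), crest coverage 71.43%
RFE    : 12/28 features (42.86%), crest coverage 100.0%
SFM    :  4/28 features (14.29%), crest coverage 28.57%
split: 109 train / 47 test
Feature Selection Matrix Dimension   LRM   RFM  Accuracy Improvement
          Initial         156 x 31 82.98 93.62                 10.64
              SKB         156 x 13 93.62 93.62                  0.00
              RFE         156 x 23 91.49 93.62                  2.13
              SFM          156 x 7 93.62 95.74                  2.12
amylum: 4 selected descriptor(s)
```

Reading the output: every sample yielded all seven crests after baseline
differencing; SKB kept 10 of 28 descriptors (35.71 %); on the held-out 47
samples the forest beats the logistic model in every row (e.g. 95.74 % vs
93.62 % for SFM), and the best selector's retained descriptors all sit on
the 480/2910 cm⁻¹ starch bands — so amylum is the constituent that
identifies tolerant varieties, exactly the signal the generator plants.

The same pipeline is scriptable end-to-end via the CLI
(`raman-rice run --seed 1 --out results/`, plus `synth`, `features`,
`select`, `classify` subcommands) and drives real instrument exports the
same way through two-column ASCII PRN files and a manifest
(`raman-rice features --manifest my_spectra/manifest.csv`).

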