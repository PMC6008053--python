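# Methods

## The measurement model

A dynamic SILAC experiment switches cells from light to heavy
Arg/Lys-containing medium and follows, per tryptic peptide, the
heavy/light MS ratio over a chase. The package models the visible
channels explicitly. At chase time *t* (days), a protein with first-order
degradation rate constant *k* (per day) retains an old (pre-existing)
fraction `f = exp(−k·t)`. Because the medium retains residual light amino
acids, a nascent molecule draws each labelable residue heavy
independently with probability `P(H)` (the label purity). For a peptide
with `n` labelable residues (`n = MC + 1`, `MC` missed cleavages):

- visible light signal ∝ `f + (1 − f)·P(L)^n` (old molecules plus
  all-light nascent molecules, which are indistinguishable);
- visible heavy signal ∝ `(1 − f)·P(H)^n` (all-heavy nascent molecules);
- mixed-label species of missed-cleavage peptides appear in neither ratio
  channel, but their detection counts (LH) — together with the all-heavy
  counts (HH) — identify the purity through the pairing ratios
  `LL : LH : HH = P(L)² : 2·P(L)·P(H) : P(H)²`. The unobservable LL term
  cancels, giving the closed form `P(H) = (2·HH/LH)/(1 + 2·HH/LH)`. The
  estimator is computed per sample (one LC-MS injection of one replicate
  and timepoint), on detection counts, not intensities; a pooled
  estimator is available for low-count designs. A sample with `LH = 0`
  and `HH > 0` saturates at `P(H) = 1` with a warning; a sample with no
  labelled species at all is an error.

The pre-existing fraction is reconstructed as
`%old = 1 − (1 − %L)/P(H)^n` with `%L = 1/(1 + H/L)`. Two exponent rules
are implemented. The default, `n = MC + 1`, counts the labelable residues
and makes the correction exact for fully tryptic peptides (`MC = 0`)
under the channel model above; the alternative `n = MC` applies one
factor of `P(H)` per missed cleavage only, leaving fully tryptic peptides
uncorrected even though a fraction `P(L)` of their nascent copies is
light. Outputs record which rule was used (config key `exponent_rule`).
Corrections that drive `%old` negative — increasingly likely for
missed-cleavage peptides of fast-decaying proteins — are excluded with
reason `negative_after_correction`.

For `MC ≥ 1` at partial purity the correction is approximate even without
noise: the heavy channel is deflated by `P(H)^n` but the visible
denominator also lacks the mixed species, leaving a downward bias in
`%old` that grows as `f` falls. At the default purity 0.8 this biases
pooled rate constants upward by roughly 3–5 % (recovered half-life
medians sit ~4 % below truth in the validation runs); the bias vanishes
as `P(H) → 1` and for fully tryptic peptides. The exact inversion of the
channel model would remove it, but the implemented correction is the
field-standard form and is retained deliberately.

## Half-life pipeline

Order of operations: fraction computation → peptide filtering →
replicate merge → outlier removal → continuous-decay exclusion →
fast-turnover censoring → fitting. Every exclusion is logged with stage
and reason.

- **Filtering.** Within each biological replicate a peptide is retained
  only if quantified at every design timepoint and its mean `%old` at t0
  exceeds 0.9 (`t0_min_old`); peptides mapping to more than one protein
  group are dropped. Replicates are then pooled.
- **Outliers.** Per protein and timepoint, values outside
  `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` are removed. Quartiles use linear
  interpolation between order statistics — stated explicitly because
  quartile conventions differ across software; with ≤2 values the fences
  cannot exclude anything.
- **Continuous decay.** Profiles whose per-timepoint means rise by more
  than `monotonic_tolerance` (default 0.05 absolute, a package choice —
  no tolerance is inherent to the rule) between consecutive timepoints
  are excluded.
- **Censoring.** k-means (`k_clusters = 6`, fixed seed, both config
  keys) on the per-protein mean-`%old` vectors; proteins in clusters
  whose centroid retains ≤50 % at day 1 are assigned "<1 day" and carry
  no numeric rate. With fewer profiles than clusters the per-protein rule
  is applied directly. Six clusters with a fixed seed is a package
  choice; the censoring outcome is governed by the centroid rule, not the
  cluster count.
- **Fitting.** All retained peptide-level points are pooled and
  `ln(%old)` is regressed on *t* **without intercept** — the model forces
  the curve through `(0, 1)` — including the t0 points by default
  (`include_t0_in_fit`; t0 points do not move a no-intercept slope but
  enter the degrees of freedom and R²). R² is the uncentered coefficient
  of determination appropriate to no-intercept regression (the centered
  form can be negative here). Fits need ≥3 positive-fraction points;
  non-positive fitted `k` marks the profile unfittable.

## Comparisons

The culture-type comparison operates on the retained peptide-level `%old`
values per protein and chase timepoint (pooling technical injections;
a `replicate_means` option averages within biological replicates first).
Proteins qualify when both conditions hold ≥2 values in every chase cell
and the per-timepoint mean differences share one sign ("always greater or
always smaller"); the per-timepoint test is Welch's two-sided t-test by
default (the unequal-variance form is the safer default; a flag restores
Student), Bonferroni-corrected over (tested proteins × chase timepoints),
with a protein called significant at ≥2 of 3 chase timepoints. Censored
proteins carry no rate to compare and are excluded. Swapping the two
conditions provably flips direction labels and preserves p-values.

The paired comparison for two-timepoint (0/7 d) designs reduces each
peptide to its decay `%old(t0) − %old(7 d)` per condition, removes
peptides with negative decay, matches peptides by sequence across
conditions, and applies a paired two-sided t-test per protein (≥2 matched
peptides) with Bonferroni over proteins.

`type_one_error_audit` validates the procedure by Monte-Carlo: matched
null pairs (same generator, independent noise) for the family-wise error
rate, and a rate-multiplier effect for power.

## Complex cohesion

Complexes with ≥5 annotated members and ≥3 numerically measured
half-lives enter; censored members are skipped. The statistic is the
sample SD (n−1 denominator) of member half-lives, compared by two-sided
Mann-Whitney against SDs of random size-matched groups drawn from the
full half-life population — without replacement within a group, with
replacement across groups and repetitions (`n_rep` default 1000, seeded;
both the repetition count and the replacement scheme are config-exposed
because neither is canonical). If every SD in both samples is identical
the tie-corrected normal statistic is undefined and the test returns
`U = n1·n2/2, p = 1`. The report includes the Spearman correlation of
complex size vs SD as a one-line diagnostic.

## Imaging decay

Puncta pulse-chase fits use the arithmetic mean puncta count per chase
day (cells with zero puncta included — dropping them would bias the mean
upward), then ordinary least squares of `ln(mean)` on chase day **with**
a free intercept, because the initial puncta number is not normalised to
one. Chase designs are taken from the input table, not hard-coded. Days
with non-positive means are dropped with a warning; ≥3 usable days are
required. A nonlinear least-squares option fits `n0·exp(−k·t)` directly;
the two differ only slightly under noise. `correlate_halflives` reports
the Pearson r (with two-sided p) between imaging- and MS-derived
half-lives.

## Synthetic-data generator

Defaults encode the emulated design: timepoints 0/1/3/7 d, 3 biological
replicates × 3 injections, heavy fraction 0.8 (final 4:1 heavy:light
medium), log-normal half-lives with median 5.4 d and log-sd 0.55
(right-skewed, spanning <1 to >20 d without tails heavy enough to break
fits), peptides per protein geometric with mean 6 (minimum 1),
missed-cleavage probability 0.2 — plausible tryptic-digest values —
multiplicative log-normal ratio noise with log-sd 0.1 (a stated
assumption; the magnitude of real SILAC ratio noise is not prescribed),
dropout probability 0.1 with per-peptide detectability drawn from
U(0.8, 1), glia-like condition multiplier 1.4 on k, and within-complex
intra-class correlation 0.5 implemented as a shared normal component on
log k. Label counts per sample are Poisson around
`label_events_per_sample` (default 5000) scaled by the mean nascent
fraction, then split multinomially into LL/LH/HH; LL is discarded as
unobservable. All draws descend from one seed through named sub-streams,
so every table is reproducible independently.

What the generator does **not** emulate: intensity-dependent or
peptide-specific ratio error, chromatographic or identification effects,
arginine-to-proline conversion, protein-abundance dynamics beyond
first-order decay, non-exponential (two-state) degradation, noise on t0
detections (t0 peptides are emitted light-only), and correlated dropout.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated error model, not robustness to every
real-data pathology.

## Validation scales and determinism

Validation uses problem sizes chosen to make the checks statistically
decisive while remaining quick: 2000 proteins for exact and stochastic
recovery (the noiseless, full-label, no-dropout limit must recover every
non-censored rate to 1e-9; at default noise the median absolute relative
half-life error stays below 10 % and the recovered median within 5 % of
the generator median), 200 matched-null simulations for the family-wise
error audit and 15 effect simulations for power, 50,000 labeling events
for purity recovery (±1 percentage point), and 500 cells/day for the
puncta worked examples so that Poisson counting error sits well below the
±0.1 d reproduction tolerance. The puncta worked-example time courses are
synthetic stand-ins generated at the published half-lives (GM130 1.9 d,
0–3 d chase; LaminB1 4.4 d, 0/1/3/7 d chase), as the original per-cell
source tables are not redistributed here. All stochastic tests fix their
seeds.

## Known limitations

- The `MC ≥ 1` correction bias at partial purity described above (~4 %
  on the recovered half-life median at purity 0.8 with 20 %
  missed-cleavage peptides).
- Purity is treated as known once estimated; its sampling error
  propagates into `%old` without being reflected in the reported
  standard errors.
- The "<1 day" censoring boundary depends on the cluster structure near
  50 % remaining at day 1; proteins just above one day can be censored
  under noise.
- Bonferroni control is conservative for correlated per-timepoint tests;
  no FDR alternative is provided by design.
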