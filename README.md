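# silac-turnover

Protein half-life analysis for **dynamic SILAC** experiments, with a
companion synthetic-data generator for validation, for proteomics groups
measuring protein turnover in cell culture (e.g. primary neuronal and
glial cultures).

In a dynamic SILAC experiment, cells grown in "light" medium are switched
to medium containing heavy isotopologues of arginine and lysine. Nascent
protein incorporates heavy residues; pre-existing protein stays light and
decays. For each peptide the mass spectrometer reports a heavy/light
ratio H/L at each chase timepoint, from which the pre-existing fraction is
reconstructed and fit with first-order decay.

## Model

For a peptide measured at time *t* (days):

- light fraction: `%L = 1 / (1 + H/L)`
- label purity: when the switch leaves residual light amino acids, a
  nascent Arg/Lys is heavy only with probability `P(H)`. From detection
  counts of mixed (LH) and fully heavy (HH) species of missed-cleavage
  peptides (two labelable residues):
  `P(H) = (2·HH/LH) / (1 + 2·HH/LH)`
- pre-existing fraction: `%old = 1 − (1 − %L) / P(H)^n`, where `n` counts
  the labelable residues (`n = MC + 1` by default, `MC` = missed
  cleavages; the per-missed-cleavage rule `n = MC` is a config option).
  Negative corrected values are excluded.
- decay: per protein, pooled peptide-level points are fit by no-intercept
  least squares `ln(%old) = −k·t`; the half-life is `t½ = ln 2 / k`, with
  the standard error of `k` and the uncentered R² as diagnostics.
  Proteins decaying too fast to fit (≤50 % pre-existing protein after one
  day, found by k-means clustering of mean %old profiles) are censored to
  "<1 day".

Around the fit sit the retention rules of the half-life pipeline
(peptides quantified at every timepoint per biological replicate, t0 mean
%old > 0.9, protein-group-unique peptides, Tukey-fence outlier removal,
continuous-decay requirement), cross-condition comparisons (per-timepoint
Welch t-tests with Bonferroni control and a ≥2-of-3-timepoints verdict;
a paired peptide-level decay test for two-timepoint designs), a
within-complex half-life cohesion test against a size-matched resampling
null (Mann-Whitney), and exponential fits to pulse-chase puncta counts
from imaging experiments.

## Worked example

Simulate a 200-protein experiment (timepoints 0/1/3/7 d, 3 biological
replicates × 3 injections, 80 % heavy medium), estimate purity, fit
half-lives and test complex cohesion:

```sh
cat > config.yaml <<'EOF'
simulation:
  n_proteins: 200
  n_complexes: 10
  seed: 42
pipeline:
  n_rep: 500
EOF
silac-turnover --config config.yaml --out demo simulate
silac-turnover --config config.yaml --out demo purity demo/label_counts.tsv
silac-turnover --config config.yaml --out demo halflife demo/peptides.tsv demo/purity.tsv
silac-turnover --config config.yaml --out demo complexes demo/halflives.tsv demo/complexes.tsv
```

which prints

```
wrote 34555 peptide rows to demo
wrote 27 purity estimates to demo/purity.tsv
200 proteins fitted, 287 exclusions logged
10 complexes, median SD 1.38 d vs null 2.68 d, Mann-Whitney p = 9.68e-05
```

`demo/halflives.tsv` then holds one row per protein:

```
protein_group  n_peptides  n_points  k_per_day  se_k        r_squared  half_life_days  censored
P00000         3           69        0.332327   0.00605263  0.977941   2.08574         0
P00001         5           138       0.181781   0.00116254  0.994428   3.8131          0
```

`k_per_day` is the first-order decay rate constant, `half_life_days =
ln 2 / k`, and `censored = 1` marks "<1 day" assignments. The complex
report shows that simulated complex co-members (intra-class correlation
0.5 on log k) have more similar half-lives than random proteins — the
median within-complex SD (1.38 d) falls well below the resampled null
(2.68 d).

Imaging time courses are fit the same way from a per-cell puncta table:

```sh
silac-turnover --out demo funcat demo/puncta.tsv
# GM130: t1/2 = 1.91 d (r^2 = 0.999)
```

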