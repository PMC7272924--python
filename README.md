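# teahopper

Dose-response analysis of herbivore-induced changes in plant metabolite
profiles, built around the tea plant / tea green leafhopper system:
potted *Camellia sinensis* plants exposed to a range of *Empoasca*
densities, with volatile (GC-MS-like) and non-volatile (LC-MS-like)
metabolite read-outs and visible leaf damage quantified from classified
leaf images.

When herbivory is quantitative rather than present/absent, each
metabolite can respond to herbivore pressure in its own way: not at all,
proportionally, or only past a threshold. `teahopper` implements the
full analysis chain for that question, plus a synthetic-data generator
with known ground truth so every stage can be validated end-to-end.

## What it computes

**Preprocessing** (`teahopper.preprocess`). Raw peak tables are
normalised to relative peak areas (RPA = peak area / internal-standard
area), field-blank corrected with non-detections floored at `100/IS`,
filtered to compounds detected in more than five samples, natural-log
transformed, screened for multivariate outliers (nearest-neighbour
distance with an exponential tail test), and autoscaled per compound.

**Constrained ordination** (`teahopper.rda`). Redundancy analysis with a
single continuous predictor x: the response matrix Y (autoscaled) is
projected onto span{1, x}; with the centred fitted matrix Ŷ_c,

    R² = SS(Ŷ_c) / SS(Y_c),     F = (R²/q) / ((1−R²)/(n−q−1)),  q = 1,

and significance comes from B permutations of x,
`p = (1 + #{F_perm ≥ F_obs}) / (1 + B)`. Compounds whose Pearson
correlation with the constrained-axis site scores is significant are
reported as **biomarkers**, ordered by |r|.

**Dose-response shape classification** (`teahopper.doseresponse`). For
each compound four mean functions compete on AIC = n·ln(RSS/n) + 2k:

| model  | mean function                | k |
|--------|------------------------------|---|
| null   | α                            | 2 |
| linear | α + βx                       | 3 |
| step   | α + Δ·1[x > e]               | 4 |
| hinge  | α + β·max(0, x − e)          | 4 |

The change point e is found by exhaustive search over midpoints of
consecutive distinct x values (≥ 2 points per segment). A winning
threshold model must also survive a case-resampling bootstrap: its 95%
change-point interval must stay strictly inside the observed x range and
its jump/slope interval must exclude zero, otherwise it is demoted to
the next-best model.

**Damage metrics** (`teahopper.damage`). Percent damaged leaf area
`D = 100·damaged/(damaged + undamaged)` from three-class pixel masks
(background never enters the ratio), per-pot means, Cohen's kappa for
classifier agreement, and a transparent nearest-centroid colour
classifier (Mahalanobis distance to per-class colour statistics).

**Synthetic experiment** (`teahopper.synthetic`). 19 pots at nominal
densities 0–2 insects/young leaf with ±0.25 jitter; ln(% leaf damage)
follows a hinge with threshold 0.6 insects/young leaf; focal-leaf damage
is mean damage with multiplicative noise calibrated to a target Pearson
correlation (default 0.71); 35 volatile-like compounds split 12 step /
11 linear / 12 null, with ln-scale Gaussian noise. The raw-peak-table
generator inverts the preprocessing so the chain is round-trip testable.

## Worked example

```sh
teahopper run --seed 1 --out out/
```

prints the ordination summary for the two synthetic data blocks:

```
                               n        r2  variance_explained_pct   pseudo_F  df1  df2      p    B  n_biomarkers
block        predictor
volatiles    density          19  0.507956               50.795583  17.549744    1   17  0.001  999            23
             ln_mean_damage   19  0.298078               29.807829   7.219225    1   17  0.002  999            19
             ln_focal_damage  19  0.207717               20.771651   4.456966    1   17  0.007  999            11
nonvolatiles density          19  0.200331               20.033080   4.258791    1   17  0.001  999             4
             ln_mean_damage   19  0.310806               31.080639   7.666508    1   17  0.001  999             5
```

Reading the first row: at this seed, final leafhopper density explains
50.8% of the variance in the 35-compound volatile profile
(F(1, 17) = 17.55, permutation p = 0.001 with B = 999), and 23 compounds
correlate significantly with the constrained axis. The per-compound
table `out/biomarkers_volatiles_density.tsv` then classifies each
biomarker's response shape; with this seed 12 step, 12 linear and 11
null shapes are recovered from a 12/11/12 ground truth. The same run
writes the non-volatile tables, the total-polyphenol model competition
(a significant negative linear trend with ln damage), and a damage-QC
table from simulated leaf images (mean kappa ≈ 0.9997).

The library surface mirrors the CLI: `simulate_*` generators,
`preprocess_peak_table`, `fit_rda` / `permutation_test` /
`select_biomarkers`, `compete`, and `run_pipeline` for the whole chain.

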