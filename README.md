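# pnquant

Quantitative pronucleus (PN) assessment for time-lapse zygote imaging.

After ICSI fertilisation, the two pronuclei — carrying the maternal and
paternal chromosomes — appear near the zygote surface, migrate inward
and grow until they fade at syngamy (~6–22 h post-injection). `pnquant`
turns time-lapse z-stacks (or pre-computed per-frame PN detection
tables) into per-embryo female/male PN growth coefficients, ranks
embryos within each patient, and tests whether the ranks predict the
chromosomal status of the resulting blastocysts from pre-implantation
genetic testing (PGT). It is aimed at embryologists and methods
researchers who want a reproducible, scriptable version of quantitative
PN morphometry, with a seeded synthetic-zygote simulator standing in
for clinical data.

## The model

PN area growth is exponential:

    f(t) = β1 · β2^t        t = hours post-ICSI

fitted by closed-form least squares on the log scale, with R² reported
on the original area scale. `β1` is the fictitious PN area at the
moment of injection (µm²) and `β2` the hourly growth factor (cohort
scale: 1.04 ± 0.017). Because β2 ≈ 1, the analysis object is β1.
Four fitting windows handle detector error structure: `original` (all
frames), `adjusted` (first/last three frames dropped), `h12` and `h14`
(from 12 h / 14 h post-insemination).

Absolute β1 is strongly heterogeneous across patients (I² > 90%), so
statistics operate on within-patient ranks: rank-stratified rate
tables, Woolf odds ratios for top-vs-last comparisons, Pearson
chi-square, Spearman correlation and Cochran Q/I².

The measurement chain before the model: variance-of-Laplacian focal
plane selection from each z-stack; PN detection (baseline classical
detector, or ingestion of external detection tables, e.g. from a
trained segmentation network); abandonment filtering of frames without
exactly two PNs; female/male assignment (earlier appearance → male,
else larger early area → male); and a cosine-similarity stability rule
(cos θ > 0 between consecutive female→male centre vectors) that
detects and corrects per-frame label flips. PGT report strings such as
`46, XN, dup (16) (p13.3p13.13) (5.7 Mb)` are parsed and classified
into seven chromosomal-error categories. See `docs/methods.md` for the
full account.

## Worked example

Simulate a 155-patient cohort with the default error model (early-stage
vacuole overcalls, mid/late overlap misses, label flips), run the full
pipeline, and test the rank → outcome association:

```python
from pnquant import SimConfig, RunConfig, run_quantify, run_stats

config = RunConfig(mode="simulate", sim=SimConfig(n_patients=155), seed=7)
result = run_quantify(config)
print(result["fits"].head(4).round(3).to_string(index=False))

report = run_stats(result["fits"], result["sim"]["outcomes"], pool_after=8)
```

which prints:

```
embryo_id    sex  variant   beta1  beta2    r2  n_points
P0000-E00 female original 226.012  1.040 0.766        55
P0000-E00 female adjusted 265.086  1.030 0.972        49
P0000-E00 female      h12 276.753  1.027 0.963        38
P0000-E00 female      h14 271.646  1.028 0.948        30
```

For this embryo the early overcalled frames drag the original-window
fit (R² 0.77) while the adjusted/12 h/14 h windows agree on β1 ≈ 270
µm² with R² ≥ 0.95 — the reason the windowed variants exist. At cohort
level the same effect shows up in the statistics (top-1 vs last-1
chromosome-normal odds ratio, female β1 ranking):

```
original  OR 1.30  [0.83, 2.03]
h14       OR 2.27  [1.44, 3.58]
heterogeneity I² = 95.5 %
```

the 14 h window recovers the outcome signal that early detection noise
dilutes, and the between-patient heterogeneity justifies ranking within
patients rather than thresholding β1 globally.

The same stages are available as a CLI for file-based workflows:

```bash
pnquant simulate --seed 7 --out-dir sim/
pnquant fit --detections sim/detections.csv --out fits.csv
pnquant stats --fits fits.csv --pgt sim/outcomes.csv --out-dir report/
pnquant classify --pgt my_pgt_table.csv --out classified.csv
```

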