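# Methods

## Problem and pipeline

In ICSI cycles, time-lapse incubators image each zygote every 10–15
minutes at several focal offsets while the two pronuclei (PNs) — the
membrane-bound structures carrying the maternal and paternal chromosomes
— form, migrate inward and grow, roughly 6–22 h post-injection. The
package quantifies PN growth and asks whether the size of the female PN
carries information about the chromosomal integrity of the resulting
blastocyst, as read out by pre-implantation genetic testing (PGT).

The measurement chain:

1. **Focal selection** (`focal`). For each time point the sharpest plane
   of the z-stack is chosen by the variance-of-Laplacian score: the 3×3
   kernel `[[0,1,0],[1,−4,1],[0,1,0]]` is convolved with the image and
   the population variance of the response over interior (non-border)
   pixels is maximised. The score is zero for constant images, invariant
   to intensity offsets and quadratic under intensity scaling. Ties break
   to the lowest plane index. The border is excluded rather than padded
   so no padding convention enters the score. Any plane count is
   accepted; the default acquisition geometry has 11 planes at −75…+75 µm
   in 15 µm steps.
2. **Detection** (`detect`). Either a baseline classical detector
   (Gaussian smooth σ = 2 px → Otsu threshold → connected components →
   keep components with area within `[min_area, max_area]` and
   circularity 4πA/P² ≥ 0.7), or ingestion of per-frame detection tables
   produced by an external segmentation model. Areas convert to µm² with
   the optics' scale, 1 px = 0.3275 µm (area × scale²), overridable in
   configuration. The detector is deliberately simple: it is adequate for
   the simulator's rendered imagery and is not meant to compete with a
   trained segmentation network on clinical images.
3. **Tracking** (`track`). Frames whose detection count differs from
   exactly two are discarded with a logged reason (the *abandonment*
   rule); the two detections are linked across frames by nearest-centroid
   matching (per-frame PN displacement ≪ inter-PN distance). Sexing uses
   two rules in fixed order: the PN appearing earlier (by at least one
   frame interval) is male; otherwise the PN with the larger mean area
   over the first three retained frames is male. Embryos tying on both
   rules are excluded as indistinguishable. Polar-body proximity — the
   manual rule — is not automated; a `sex_override` column is honoured on
   ingestion instead. Finally, label stability is enforced: for every
   consecutive frame pair the cosine between the female→male centre
   vectors must be strictly positive; a violating frame has its labels
   swapped (recorded in `swap_events`) and is re-evaluated, and frames
   failing under both labelings (cosine exactly zero) or with coincident
   centres are discarded. Corrections are applied sequentially, so each
   pair is evaluated after the previous frame's correction.
4. **Growth model** (`growth`). PN area follows `f(t) = β1 · β2^t` with
   `t` in hours post-ICSI, so β1 is the (fictitious) area at the moment
   of injection and β2 the hourly growth factor. Fitting is ordinary
   least squares of ln(area) on t — closed-form, deterministic, no
   initialisation. R² is reported on the *original* area scale against
   back-transformed predictions, since the published goodness-of-fit
   range (98–99.99%) refers to that scale. Four windowing variants
   address detector error structure: `original` (all frames), `adjusted`
   (first and last three frames dropped: they carry most recognition
   error and the largest leverage), `h12` and `h14` (frames from 12 h /
   14 h onward). β1 always refers to the t = 0 intercept. A fit needs at
   least 4 points (2 parameters + 2 residual df); variants whose window
   retains fewer points are marked unavailable, not fatal.
5. **Karyotype classification** (`karyotype`). PGT report strings are
   tokenised into whole-chromosome gains/losses, segmental
   duplications/deletions (band range, size in Mb) and mosaic
   annotations, then classified into seven categories (chromosome-normal,
   sole mosaic, sole aneuploidy, sole del/dup, euploidy with errors,
   aneuploidy with errors, complex). Chromosome-normal and sole-mosaic
   embryos form the "normal group" used by the statistics, since sole
   mosaicism arises from post-zygotic mitotic errors. For PGT-SR couples,
   parental coincidence is resolved at chromosome level (band-level
   matching is under-specified in clinical shorthand): an embryo error on
   a chromosome involved in the parental rearrangement is *coincident*.
   A single all-mosaic event list is classified sole-mosaic even when the
   event is segmental.
6. **Rank statistics** (`ranking`). β1 is strongly heterogeneous between
   patients (Cochran Q / I² confirms this on simulated cohorts), so
   outcome comparisons are made on within-patient ranks (1 = largest β1;
   ties break by embryo id for deterministic reruns; ranks beyond K pool
   into a ">K" stratum, K = 8 for PGT tables and 10 for blastocyst
   formation tables). The battery: per-rank rate tables; Woolf log
   odds ratios with 95% CI `exp(ln OR ± 1.95996·√(Σ 1/cell))` for
   top-k vs last-k comparisons (Haldane +0.5 on zero cells, flagged);
   Pearson chi-square on R×2 tables without continuity correction;
   Spearman mid-rank correlation; and fixed-effect Cochran Q with
   I² = max(0, (Q − df)/Q)·100, groups weighted by n/SD². No
   multiple-testing correction is applied, matching the source analysis;
   users comparing many strata should adjust externally.

## Synthetic-data generator

Real clinical images and PGT tables cannot be redistributed, so the
`simulate` module generates every pipeline input with known ground
truth. It emulates:

* **Geometry** — two PNs inside a 250 µm well at 0.3275 µm/px; centres
  migrate from the periphery toward the zygote centre along parallel
  lines with a fixed 36 µm perpendicular separation, so the female→male
  direction is stable (the quantity the cosine rule protects).
* **Growth** — `area(t) = β1 · β2^t` with per-embryo β2 drawn from a
  truncated normal (mean 1.04, SD 0.017, bounds [1.01, 1.11]); the male
  β2 is a small perturbation (SD 0.004) of the female's, since both PNs
  share the zygote. β1 has between-patient SD 80 µm² around a 250 µm²
  mean and within-patient SD 30 µm²; the male PN is ~15% larger at
  equal time. Areas carry multiplicative lognormal noise, default
  σ = 0.02 — the level consistent with the observed 98–99.99% R² range.
* **Timing** — male PN appears 6.5–8 h post-ICSI; the female follows
  0.5–1.5 h later (8% of embryos draw a long 1.5–6 h delay, giving the
  late-forming tail); both fade at 20–23 h; frames every 15 min from 5 h.
* **Detector error modes** — early-stage vacuole overcalls (spurious
  detections bringing pre-2PN frames to two calls, rate 0.25 per
  eligible frame, hence concentrated before 12 h), overlap-merged misses
  from 14 h onward (rate 0.02), and per-frame female/male label flips.
  Detection tables carry a provisional per-frame sex label — the output
  a per-frame classifier would produce — and the tracker audits those
  labels with the cosine rule; label flips are injected by flipping the
  provisional labels.
* **Outcomes** — P(normal group) = logistic(α + γ·z) with z the
  within-patient β1 z-score; defaults α = 0.06, γ = 0.23 are calibrated
  so the top-1 and last-1 strata sit near 58% and 45% normal rates.
  Non-normal embryos draw a category from a configurable distribution
  and a karyotype string is synthesised from the report grammar, so the
  parser is exercised on generated text, not only on literal examples.

Everything is deterministic under (config, seed). What the generator
does **not** model: cytoplasmic texture, nucleolus precursor bodies,
polar bodies, multi-embryo wells, illumination drift, or any real
optics beyond plane-dependent Gaussian blur in the renderer. Passing
tests therefore demonstrate correctness of the measurement and
statistics machinery under the stated generative assumptions, not
detector performance on clinical imagery.

## Numerical choices and degenerate inputs

* Log-scale fitting requires strictly positive areas; non-positive areas
  raise. A constant trajectory fits exactly with β2 = 1.
* R² of a zero-variance series is defined as 1 when residuals vanish, 0
  otherwise.
* The cosine rule uses strict inequality; cosine exactly 0 fails both
  labelings and discards the frame.
* Ranking requires finite positive β1 and unique embryo ids per patient.
* Zero-variance groups in the heterogeneity test get their weight capped
  at the largest finite weight and are flagged.
* Percentages in rate tables round to 2 decimals; odds ratios and CIs
  are reported unrounded and rounded only for display.

## Problem sizes

Test and benchmark cohorts are sized for tight feedback loops: ~500
embryos for calibration checks (matching the scale at which cohort
moments stabilise), 20 replicates for recovery medians, 2 000 patients
for the null outcome model, and 155 patients per replicate for the
calibrated model — the cohort size of the clinical analysis the
statistics mirror.

## Known limitations and source inconsistencies

* The exponential-vs-alternatives comparison (`compare_model_families`)
  is a report, not a decision rule: a raw-scale quadratic (which nests a
  linear trend) can match a gentle exponential's R² arbitrarily closely,
  so "alternatives fit worse than 0.90" cannot hold in general. The
  exponential is preferred for parsimony and because its parameters
  (intercept at ICSI, hourly growth factor) are biologically
  interpretable and extrapolate sensibly.
* Per-trajectory R² ≥ 0.98 requires the growth amplitude within the
  fitting window to exceed the area noise roughly seven-fold; with
  β2 ≈ 1.04 over a ~14 h window this holds at noise σ ≈ 0.02 in central
  tendency but not for the slowest-growing (β2 ≈ 1.01) or late-forming
  trajectories, whose R² is structurally lower.
* Three published worked-example values are internally inconsistent with
  their own printed inputs, and the corresponding acceptance assertions
  fail by design rather than being loosened: the all-stage recognition
  accuracy (the printed percentage corresponds to dropping the missed
  term from the printed formula), the upper CI bound of the first odds
  ratio (Woolf reproduces 2.63, not the printed 2.64, while the other
  five printed bounds reproduce exactly at 2 decimals), and the male
  formation-table chi-square (the printed statistic matches the printed
  p-value but not the printed table, which yields 12.20).
* Published heterogeneity values (Q = 96.32 with df = 183 yet
  I² = 95.6%) contradict the standard I² formula; the package implements
  the standard formula and makes no attempt to reproduce that triple.
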