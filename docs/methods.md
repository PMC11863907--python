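# Methods

## Occupancy model

A cfDNA fragment is a 0-based half-open genomic interval; fragments are
strand-agnostic (cfDNA is double-stranded), and BAM input contributes one
fragment per properly paired template (leftmost mate start + template
length), excluding duplicate, secondary, supplementary and MAPQ < 20
reads. The MAPQ/duplicate defaults are ordinary WGS practice, exposed as
options. Occupancy analyses use fragments with length in [120, 180] bp —
bounds inclusive, the conservative reading of a "120–180 bp" range — to
select nucleosome-protected DNA.

**Windowed occupancy.** The genome is tiled into consecutive,
non-overlapping windows (default 10 kb; the last window of a chromosome
may be shorter). A window's value is its mean per-bp fragment coverage:
fragments spanning a boundary contribute to each window proportionally to
the overlap, so the width-weighted sum of values equals the total
fragment bases — a conservation law the tests assert. Tiling rather than
a sub-window step is the default because the downstream region counts
presuppose a fixed partition; `step < bin_size` is available for
sensitivity analyses. Coverage averaging (not fragment-midpoint counting)
is the primary definition.

**Depth normalization.** Each track is divided by its width-weighted
genome-wide mean coverage, making the normalized mean exactly 1
(tolerance 10⁻⁶ in the tests) and tracks comparable across sequencing
depths; duplicating every fragment leaves a normalized track unchanged.
Read-count and mean-coverage normalizations differ only by a constant
under a fixed length filter, so the mean-coverage form is used. Zero
windows are retained (value 0) and handled by the stability filter, not
dropped.

## Differential-occupancy calling

Within a condition with ≥ 2 samples, a window's relative deviation is
RSD = sd/μ with the n−1 standard deviation (the estimator is a package
choice; nothing downstream is sensitive to n−1 vs n at the cohort sizes
involved). A window is **stable** when RSD is defined (μ > 0) and
**strictly** < 0.5. Windows with μ = 0 are unstable by definition — no
relative change can be formed there.

For windows stable in both conditions, the signed relative change is
Δ = (μ_post − μ_pre)/μ_pre; Δ > 0.4 calls a gained-nucleosome region and
Δ < −0.4 a lost-nucleosome region, both strictly. The pre-treatment
denominator is the primary definition; a symmetric denominator
((μ_pre + μ_post)/2) is available via an option. Regions are single
windows, reported in genomic order; adjacent calls are not merged, so
region counts are window counts. Progression samples never enter calling; they
are profiled against called regions downstream. The procedure is
deliberately free of p-values and multiple-testing control.

Both thresholds (0.5, 0.4), the window size and the length bounds are
plumbed through the config/CLI; the resolved defaults are exactly this
configuration, so a full-scale cohort run needs no extra flags.

## TFBS footprint read-outs

Binding sites come from BED (ChIP-seq peaks, motif scans or database
exports); the center is floor((start+end)/2). `select_top_fraction`
keeps the ceil(f·n) strongest sites with ties broken by genomic position,
making the selection deterministic and nested across fractions.

**Aggregate profiles** average, with equal weight per site, the per-bp
normalized coverage in ±flank bp around each center (orientation flipped
for "−" sites; "." is treated as "+"), then average samples with equal
weight within each condition. Offsets are multiples of `step` (default
10 bp, flank 2000 bp — presentation defaults), each averaging the per-bp
curve within ⌊step/2⌋ bp. Sites whose flanks cross a chromosome edge are
dropped.

**Activity scores.** One score per sample per TF: the mean (over sites)
of the mean normalized coverage in [center − h, center + h], h = 15 bp by
default. A single-bp read-out (h = 0) is almost always 0 or 1 at 0.1×
coverage, so the ±15 bp window is the practical default; h is an option
and h = 0 reproduces the literal center-base reading. Scores use
normalized coverage so they are comparable across samples. The sign
convention, asserted end-to-end against generator truth: more TF binding
→ deeper footprint → lower center depth → lower score, and expression of
the factor's program correlates negatively with the score. Correlations
(Spearman/Pearson) and the Mann–Whitney U comparison report nominal
two-sided p-values; no multiple-testing correction is applied. Expression
is consumed as provided (TMM-FPKM semantics), never normalized here.

## Synthetic cohort generator

The generator produces the structure the analyses assume, on a flat
2 × 10 Mb two-chromosome genome by default, with all randomness flowing
from one seed through a spawned child stream per sample (adding a sample
does not perturb the others; outputs are byte-identical across reruns).

* **Fragment sizes** follow a three-component normal mixture truncated to
  [30, 400] bp: chromatosome N(165, 5), core particle N(150, 5),
  TF-protected N(50, 10). The component locations/scales are the stated
  protection modes; the weights (0.55 / 0.35 / 0.10) are the package's
  choice of a realistic mononucleosome-dominated profile that keeps all
  three peaks detectable. With 10⁶ draws the 1-bp histogram argmax
  recovers each mode to the histogram's granularity (165 and 150 exactly;
  the broad sd-10 short component to within ~1–2 bp).
* **Two channels.** Nucleosome-sized fragments carry the window
  structure: per window, the expected count is proportional to a window
  multiplier, perturbed by multiplicative Gaussian noise (relative sd
  0.1 by default — the post-normalization variability the stability
  filter sees). Short TF-protected fragments are an unstructured
  genome-wide background. Separating the channels keeps the realized
  per-window RSD at the configured value instead of adding binomial
  thinning noise from the length filter.
* **Planted differential windows** multiply the nucleosomal intensity of
  the affected condition by (1 + effect) — post-treatment carries the
  full effect, progression retains half (gained regions decline at
  progression but stay above pre-treatment). The effect is modeled at
  the level of the whole plasma pool, i.e. as treatment-level chromatin
  remodelling, not confined to the tumor compartment: a tumor-confined
  *decrease* can never exceed the tumor fraction in magnitude, so
  condition-level effects are the only way a ±0.6 planted change is
  recoverable at tumor fractions of 0.3–0.5 — and treatment plausibly
  remodels the entire cfDNA pool (tumor kill, marrow and immune
  turnover). Tumor fraction consequently acts only on footprints (next
  item), and the planted-window channel is deliberately independent
  of it.
* **TF footprints** live in the tumor compartment. Each fragment is
  tumor-derived with probability = the sample's tumor fraction. Per TF,
  sites are placed uniformly (default 500, strengths U(0,1)), and each
  site is open in a given condition with probability = the TF's activity.
  Tumor fragments overlapping an open site's footprint interval (±25 bp
  around the center) are replaced, count-conserving, by ~50 bp
  TF-protected fragments flanking the interval. One mechanism thus
  produces both the center dip (expected normalized center depth
  1 − tumor_fraction × activity, recorded in the truth table) and the
  short-fragment size component, and the dip deepens monotonically with
  either factor.
* **Expression** for each simulated TF gene is
  max(0, a − b·expected_center_depth + N(0, σ)) with defaults
  (a, b, σ) = (10, 10, 1), giving a clearly negative depth–expression
  link at cohort size 30 without being noise-free.
* **Phasing.** Periodic nucleosome positioning (dyad-anchored midpoints
  on a 200 bp repeat) is available behind a flag and off by default:
  window-level analyses do not need it, and only profile oscillations
  around dyads would.

Reference cohorts: `default_cohort_config` (6 pre + 6 post at 0.1×,
tumor fractions spanning 0.3–0.5 per arm, 30 gained + 30 lost windows at
±0.6, three TFs with treatment-shifted activities) and
`footprint_cohort_config` (30 single-condition samples, tumor fractions
0.1–0.6 matching the broad range liquid-biopsy cohorts show, TF
activities 0.1/0.5/0.9). These sizes keep the full suite and the
calibration script in the tens of seconds on one CPU while leaving the
recovery margins comfortably away from the thresholds.

**What the simulations do not show.** The generator has no sequence, no
GC or mappability structure, no nucleosome phasing by default, no
copy-number variation, and a flat healthy background; passing its
recovery tests demonstrates that the estimators implement their
definitions and that the thresholds behave as specified — not that real
cfDNA at 0.1× will yield comparable recall, which depends on biological
window-to-window variability that the noise parameter only summarizes.

## Numerical choices and degenerate inputs

Strict inequalities at both caller thresholds; RSD at exactly 0.5 is
unstable and |Δ| at exactly 0.4 is not called (asserted against an
independent enumeration). Undefined quantities (RSD at μ = 0,
correlations of constant vectors, peak ratios over empty windows) are
reported as explicit markers (NaN/None), never coerced to 0. Histogram
peak ties resolve to the smallest length; top-fraction ties to the
earliest genomic position. Empty fragment files are valid (empty sets);
all-zero coverage is an error at normalization time ("no coverage").
Fragment-size histograms live on [1, 500] bp with an overflow tail
excluded from peak searches.

## Known limitations

* No GC/mappability *correction* of coverage; GC and CNV overlap are
  post-hoc region-level checks only.
* Per-bp coverage arrays (aggregate profiles) are materialized per
  chromosome, appropriate for the simulated genomes and for targeted
  site panels; a streaming implementation would be needed for
  genome-wide per-bp work on full human chromosomes.
* Conditions are pooled groups; no paired per-patient contrast.
* The caller reports no uncertainty; it is a faithful implementation of
  a threshold procedure, and its operating characteristics should be
  established per dataset (e.g. by label permutation outside this
  package).
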