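# Methods

`oometh` implements the computational stages of a single-oocyte methylome and
imprinting-expression analysis: quality control and tiling of sparse
single-cell bisulphite data, a shuffled-pseudobulk consensus caller for
differentially methylated regions (DMRs), qPCR ΔCt statistics with
allele-specific percentage splits, clone-level bisulphite comparisons, small-RNA
counts-per-million tests, and variable-gene selection with hierarchical
clustering. A simulation module generates every input with known ground
truth, so each stage is testable end to end without sequencing data.

## Single-cell methylomes, QC and quantification

A single-oocyte bisulphite methylome is a sparse set of per-CpG calls: at
each observed CpG the cell reports methylated or unmethylated (one call per
CpG in single-cell data; pooled data may carry arbitrary counts). Two QC
filters remove failed cells:

* **global methylation > 50%** — mature oocytes are globally hypomethylated
  relative to somatic cells, so a high global level indicates contamination
  (e.g. cumulus cells) or conversion failure;
* **X-chromosome CpG-island methylation > 16%** — X CGIs are essentially
  unmethylated in oocytes; elevated levels again indicate somatic
  contamination.

Both rules are strictly-greater-than: a cell at exactly the boundary passes.
The global fraction is computed over autosomal calls only, decoupling the two
criteria (whether the X belongs in the global filter is not externally
specified; excluding it is this package's documented choice). A cell with no
X-CGI calls has that criterion skipped and is flagged.

Quantification is always **call-weighted pooling**: the methylation of a
region or tile over a set of cells is pooled methylated calls divided by
pooled total calls — the average across all CpG sites — never a mean of
per-cell fractions. A feature covered by no call is *missing*, not 0%.

Tiles are consecutive, non-overlapping windows of exactly 100 CpGs per
chromosome; the trailing remainder is dropped so every tile has identical
CpG resolution (this keeps the support of the per-tile test comparable
across tiles).

## Consensus DMR calling

Per-cell data are too sparse to test directly, so the caller:

1. partitions each condition's cells into pseudobulks of at most nine cells
   — `g = max(2, ceil(n/9))` groups with sizes differing by at most one
   (41 cells → 9,8,8,8,8). The ceiling rule keeps groups at or below nine
   and yields e.g. five groups of 7–8 for 37 cells;
2. tests each tile with a **weighted logistic regression**: one observation
   per pseudobulk, the binomial methylated proportion regressed on the
   condition indicator with prior weight equal to the pseudobulk's total
   calls, and a two-sided Wald test on the condition coefficient. A tile is
   testable in a shuffle only if every pseudobulk has at least `min_calls`
   (default 10) calls in it;
3. adjusts the testable tiles' p-values within the shuffle by
   Benjamini–Hochberg;
4. repeats the whole procedure `n_shuffles` (default 100) times with freshly
   shuffled pseudobulk memberships; a tile's **support** is the number of
   shuffles with q < 0.05;
5. calls a consensus DMR when the observed merged-all-cell difference is at
   least 10% in absolute value **and** support reaches at least 70 of 100.

**Closed form and what shuffling does.** With a single binary covariate and
call-count weights, the binomial-GLM log-likelihood depends on the data only
through the pooled per-condition counts (each observation contributes
weight × proportion = its methylated calls). The MLE fitted probabilities are
therefore the pooled per-condition proportions, the condition coefficient is
their logit difference, and its Wald variance is
`1/(T_A p_A q_A) + 1/(T_B p_B q_B)` with `T` the pooled calls. The
implementation evaluates this closed form, vectorised over tiles; it is
numerically identical to fitting the GLM per tile (verified against
statsmodels in the test suite to ~1e-10). A consequence worth stating
plainly: the per-tile p-value is the same in every shuffle, so shuffling the
pseudobulk memberships changes a shuffle's outcome only through (a) which
tiles pass the per-pseudobulk minimum-calls filter and (b) the composition of
that shuffle's BH family. The consensus over shuffles therefore stabilises
testability and family composition — the quantification biases the repeated
shuffling is designed to average out — rather than re-randomising the test
statistic itself.

Tiles with a methylated proportion of exactly 0 or 1 in either condition
have an infinite logit (perfect separation); they fall back to a
likelihood-ratio chi-square test (1 df) and are flagged. Tiles testable in
fewer than half the shuffles are flagged `low_testability`.

Randomness: one master seed spawns an independent child stream per shuffle
(`numpy` `SeedSequence.spawn`), so any shuffle is reproducible in isolation
and the whole procedure is deterministic given (seed, inputs, parameters).

## qPCR ΔCt statistics

Technical replicates are averaged per biological replicate (wells spanning
more than 1 Ct are flagged, never auto-excluded — the 1-cycle flag is a
quality aid only). ΔCt is Ct(target) minus the arithmetic mean of the
housekeeper Cts of the same sample (one housekeeper within a tissue, three
for multi-tissue comparisons; the arithmetic mean of Cts is the geometric
mean of expressions). Relative expression is summarised as the geometric
mean of 2^−ΔCt with geometric SD = 2^sd(ΔCt) (exactly 1 when replicates
agree); the per-replicate ΔCt values are returned for significance testing,
since ΔCt is the (log-scale, approximately normal) quantity.

Allele-specific assays give ΔCt = Ct(maternal assay) − Ct(paternal assay)
and the percentage split

    paternal% = 100 · 2^ΔCt / (1 + 2^ΔCt),   maternal% = 100 − paternal%.

This is the unique sum-to-100 form consistent with the ΔCt definition at
efficiency 2: for a true paternal fraction f, ΔCt = log2(f/(1−f)) and the
formula returns exactly 100·f. (A commonly printed variant,
100/(2^ΔCt − 1), is internally inconsistent — negative for ΔCt ≠ 0 and
divergent at ΔCt = 0 — and is deliberately not used.) The split is strictly
increasing in ΔCt with limits 0 and 100 approached but never attained.
Primer efficiency is assumed to be exactly 2; no efficiency correction is
applied.

## Clonal bisulphite comparisons

Each clone (sequenced molecule) contributes its methylation fraction over
non-missing CpGs; the region total is call-weighted. Groups are compared
per region with a two-sample Kolmogorov–Smirnov test on the clone fractions,
Holm–Šídák-corrected across regions. Because clone fractions take few
distinct values, ties dominate; D uses the right-continuous ECDF with ties
collapsed, and the exact p-value is the tie-aware permutation probability
P(D* ≥ D), computed by an integer lattice-path count over the pooled tie
groups (O(n_A·n_B) dynamic programming, exact arithmetic). Exact mode is
used when n_A·n_B ≤ 10,000, otherwise the asymptotic Kolmogorov
approximation with effective size n_A·n_B/(n_A+n_B). Both modes are exposed
since either convention may be wanted.

## Multiple testing

* `fdr_bh` — Benjamini–Hochberg step-up: q(i) = min over higher ranks of
  m·p(j)/rank(j), capped at 1.
* `holm_sidak` — step-down: sort ascending, adjusted(i) =
  1 − (1 − p(i))^(m − i + 1), cumulative maximum along the sorted order,
  capped at 1.

Both are implemented directly (a few vectorised lines) and are validated in
the tests against statsmodels and against definition-level oracles that
bisect over the rejection level.

## Expression matrices

`log2_rpm` computes log2(count/library-total × 10⁶ + 1); the +1 pseudocount
keeps zeros at zero and all values finite (the upstream engine's exact
transform is not reproduced bit-for-bit — this is a documented
approximation). Variable genes are selected on the SD excess over an
intensity-matched trend: genes are ordered by mean expression, the expected
SD at each mean is a centred running median (window 51 genes), and a gene is
selected when observed SD − trend SD exceeds the threshold (default 0.528 on
the log2 scale). The raw excess values are always emitted so alternative cut
rules can be applied. Selected genes are clustered by agglomerative
hierarchical clustering (Euclidean distance, complete linkage by default —
the common heatmap convention; both are parameters) and the dendrogram cut
into k clusters (default 5). PCA of cells is provided as plumbing only.

## The simulators

`simulate_methylomes` emulates the oocyte setting:

* **Bimodal genome** — chromosomes are segmented into domains of 500–3,000
  CpGs; each domain draws a latent methylation level from a Beta
  distribution centred at 0.85 (hypermethylated, probability 0.40) or 0.05
  (hypomethylated), concentration 60. Oocyte methylomes genuinely consist of
  such hyper/hypomethylated domains; no generative model is externally
  specified, so any bimodal choice is acceptable and all parameters are
  exposed in `SimConfig`.
* **Imprinted panel** — 19 maternal gDMRs (latent 0.86–0.96), 3 paternal
  gDMRs (0.02–0.08) and 2 secondary DMRs (0.40–0.60), each 30 CpGs,
  round-robin across autosomes; 20 hypomethylated CpG islands (0.01–0.05) on
  a 20,000-CpG X chromosome feed the QC filter.
* **Cells** — each cell observes an independent Binomial(coverage) subset of
  CpGs (default rate 0.15; real per-oocyte coverage depth is a free
  parameter, not an estimate) with one Bernoulli call per observed CpG.
  Real scBS-seq coverage is correlated along the genome; an optional
  `coverage_mode="blocks"` draws geometric covered/uncovered runs instead.
* **Spikes** — a configurable number of 100-CpG tiles (default 50) on
  autosomes, avoiding the annotation panel, shifted in condition B by the
  effect size (default 0.30) towards 0.5 so the shift stays in [0, 1];
  residual clipping is warned about and the realised per-tile shift is
  recorded in the truth table.

Reference scale: 2 × 40 cells, 500,000 autosomal CpGs (5,000 tiles). One
simulation plus a full 100-shuffle consensus run takes a few seconds on one
core, so the null-control study (20 independent runs) stays under a minute.

What the simulation does **not** model: read-level artefacts (bisulphite
conversion error, mapping bias), genome-correlated coverage by default,
per-cell biological heterogeneity (a logit-scale per-cell jitter is
available via `cell_noise_sd` but defaults to 0), and linkage between
neighbouring CpG states beyond domain structure. Passing tests therefore
demonstrate the correctness and calibration of the procedures under clean
binomial sampling, not robustness to those real-data artefacts.

`simulate_ct_experiment` encodes expression in Ct space: a target's true Ct
is the housekeeper-mean Ct minus log2(relative expression), plus a
per-sample loading offset (which cancels in ΔCt) and Gaussian noise per
technical replicate (default SD 0.2 cycles, 4 biological × 3 technical
replicates). Allelic pairs are built so the noiseless ΔCt equals
log2(f/(1−f)) exactly. `simulate_clone_sets` draws independent Bernoulli
clone states (default 24 clones). `simulate_count_matrix` draws
negative-binomial counts (variance μ + αμ², default dispersion α = 0.1,
baseline mean 100) with log-normal library-size factors (CV 0.15) and
designated fold-changed features in the second group.

All generators require an explicit seed (never defaulted) and are
bit-reproducible.

## Numerical choices and edge cases

* Coordinates are 0-based half-open internally; coverage files are 1-based
  inclusive and BED 0-based half-open, converted at the readers/writers.
* Degenerate tile tests: both conditions all-0 (or all-1) give p = 1; other
  separations use the LRT fallback; `xlogy` handles 0·log 0 at boundary MLEs.
* `cpm_and_test`: identical groups are reported as t = 0, p = 1 (rather than
  the 0/0 NaN of the raw statistic); zero within-group variance with a
  non-zero difference is reported as p = 0 with infinite t.
* Sorting is always stable (mergesort) so tied p-values adjust
  deterministically.
* Geometric SD of a single replicate is undefined and returned as NaN.

## Known limitations

* The consensus caller tests a two-group contrast only; covariates and
  smoothing-based DMR detection are out of scope.
* The per-shuffle test assumes binomial counts within pseudobulks; true
  biological overdispersion between cells would make the per-shuffle
  p-values conservative or anti-conservative depending on its structure, and
  is not corrected for.
* The variable-gene statistic is one reasonable reading of an
  SD-versus-trend rule; the exact statistic used by interactive tools
  differs in detail, which is why the raw excess values are emitted.
* Exact KS mode is quadratic in the sample sizes and capped at
  n_A·n_B ≤ 10,000 by default.
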