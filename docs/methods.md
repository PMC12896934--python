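# Methods

## Design and quantities

The package analyses a three-group, one-factor expression design: two
parental lines and their F1 hybrid, each with biological replicates
(default 5). All heterosis quantities are computed from per-group mean
abundances on the linear (FPKM-like) scale, reading "mid-parent value" as an
arithmetic mean of expression:

- MPV = (mean_parentA + mean_parentB) / 2
- MPH% = 100 · (mean_hybrid − MPV) / MPV
- BPH% = 100 · (mean_hybrid − high_parent) / high_parent, where high_parent
  is the larger parental mean (ties resolved to parentA and logged; BPH is
  unaffected because the means are equal).

MPH ≥ BPH holds identically because the high-parent mean is never below the
MPV. Genes with MPV below `min_mpv` (default 1 abundance unit) get undefined
MPH/BPH — percentage deviations from a near-zero baseline are numerically
meaningless — and are excluded from classification but kept in every output
with their count logged.

## Pattern classification

Classification is driven entirely by the significance calls of the two
hybrid-vs-parent contrasts, so there is a single source of truth for
"significantly up/down":

- transgressive_up: up vs both parents; transgressive_down: down vs both.
- dominant_like: significant vs exactly one parent (direction-agnostic; the
  rare discordant case — up vs one parent and down vs the other — is left
  unclassified).
- additive_like: significant vs neither and |MPH| ≤ `additive_band`
  (default 20%). Only the transgressive classes are standard terminology;
  the dominant/additive labels are a labelled convenience extension.

Two threshold sets exist deliberately. DEG *lists* use the conventional
gates p < 0.05 **and** |log2FC| > 1 (`DEGThresholds` defaults; raw p by
default, BH-adjusted p behind `use_adjusted`). The *pattern classifier*
defaults to significance only (`PatternCallConfig.thresholds` with
`lfc_cutoff = 0`): transgressive expression is defined by being
significantly outside the parental range, and a hard fold-change gate would
make the classifier blind to any real effect at or below the gate no matter
how many replicates are available — an estimate of the gate, not of the
biology. Both gates are configurable, and
`run_contrast`/`apply_calls` let callers re-derive calls under either.

`intersect_upregulated` (the intersection of the two up-regulated DEG sets)
equals the transgressive_up set by construction when fed the same DEG
records; the pipeline asserts this equivalence on every run. Candidates are
transgressive_up genes with BPH strictly > 0, sorted by descending BPH.

## Normalization

`normalize_fpkm` implements the textbook formula
count · 10⁹ / (length · library_size). Without gene lengths every gene is
treated as 1 kb (CPM); all downstream statistics are per-gene, hence
invariant to the length factor. Two library-size estimators are available:

- `"total"` — the sample's total counts (the classical FPKM denominator);
- `"median_ratio"` (pipeline default) — median-of-ratios size factors
  against a geometric-mean reference, with a second pass restricted to the
  ~30% of genes with the least between-group variation after pass one.

The robust option matters in exactly the regime this design targets: when a
sizeable block of genes is transgressively up-regulated in the hybrid, the
hybrid's total counts inflate and total-count normalization systematically
depresses every other gene in that group (in simulations with 20% 2-fold
overdominant genes, unchanged genes acquired an apparent log2FC of about
−0.5 versus a parent). Median-of-ratios removes most of that shift and the
stable-gene second pass removes the remainder (residual |log2 bias| ≈ 0.04).

## Differential expression

Tests run on log2(abundance + c), c = 1 (shared with `log_transform` and
the fold-change pseudocount; fold change is
log2((mean_test + c)/(mean_ref + c)) on the linear scale).
`run_contrast` defaults to a variance-moderated t: per-gene pooled
variances are shrunk toward an empirical-Bayes scaled-inverse-χ² prior
fitted across all genes by method of moments on log s² (trigamma
inversion), and the t statistic uses the posterior variance with
correspondingly augmented degrees of freedom. At 5 replicates per group
this is the standard remedy for noisy per-gene variances; in the simulated
design it lifts per-side power at a 2-fold effect from ~0.78 to ~0.9 while
keeping the null rejection rate at the nominal 5%.

`test_gene` is the isolated per-gene contract — plain Welch t with
Welch–Satterthwaite degrees of freedom — and `run_contrast(...,
moderation=False)` reproduces it exactly; an exact count-based test could
be substituted behind the same signature. Degenerate genes follow a
documented rule: both groups constant and equal → p = 1; constant but
unequal → exact two-sided Mann–Whitney p. Benjamini–Hochberg adjustment is
applied across all tested genes of a contrast. Genes are pre-filtered by
mean abundance ≥ 1 (configurable) across all samples.

## Trait statistics

One-way layouts are compared with Tukey's HSD: pairwise p-values from the
studentized range on the pooled ANOVA error (Tukey–Kramer for unbalanced
groups; `scipy.stats.tukey_hsd`). Compact letter displays use the
insert-and-absorb algorithm, which guarantees soundness (significant pairs
never share a letter) and completeness (non-separated pairs always do);
letters are ordered so 'a' marks the highest mean. Gene–trait association
uses Pearson r over the samples shared between the expression matrix and
the trait table, on log2 abundance by default (stabilizes r against
high-expression outliers; configurable). Stars follow 0.05/0.01/0.001.
Per-cell stars are reported without multiple-testing correction by default,
with BH available as an option. Constant vectors yield a flagged undefined
cell, never a fabricated value.

## Networks and enrichment

Hub genes are the top-k nodes by degree of the subgraph induced on the
query list within a user-supplied undirected edge list (deduplicated,
self-loops dropped); ties break lexicographically so ranks are
reproducible. Degree is the documented hub criterion; the ranking function
is isolated so alternative centralities can be added. Over-representation
uses the upper-tail hypergeometric p (k = 0 included, so empty overlaps
give p = 1) against an explicit universe — by convention the expressed
genes, the defensible background — with set memberships intersected with
the universe and BH adjustment across sets.

## Synthetic data

The simulator emulates the target design — ~20,000 genes, three groups of
five biological replicates — not sequencing itself (no reads, isoforms,
batch effects or zero-inflation). Per gene, one inheritance mode is
allocated by largest-remainder rounding of the configured fractions
(defaults: 20% additive, 10% each dominant-high/low, 20% overdominant, 10%
underdominant, 30% null) and defines the hybrid mean from the parental
means: mid-parent (additive), either parent (dominant), effect_size ×
max(parents) (overdominant) or min(parents)/effect_size (underdominant),
with effect_size 2 by default. Baseline parental means are log-uniform on
[20, 2000] (an FPKM-scale dynamic range); non-null genes give the second
parent a fixed 2-fold offset with random direction. Counts are
negative-binomial with variance μ + φμ² (φ = 0.1 default; φ = 0 is the
Poisson limit), scaled by per-sample library factors uniform on (0.7, 1.3).
Everything derives from one integer seed; identical configurations are
bit-identical.

Trait vectors are linear read-outs: trait(s) = Σ_g w_g · z_g(s) + N(0,
noise_sd), where z_g is the per-gene z-score of log2(CPM + 1) across
samples. With zero noise and one driver the trait is an affine image of
that gene's log expression, so its Pearson correlation with the driver is
exactly ±1 — a sharp test anchor. Because the generator couples traits to
total-count CPM, exact-correlation checks analyse on that same scale.

What passing tests do and do not show: recovery and calibration results
hold for this generative model — independent NB noise, clean group
structure, no batch or length effects, no outlier samples. They demonstrate
the statistical machinery is correct and well-calibrated, not that any
particular recall will be achieved on real tissue data, where dispersion
varies per gene and confounders exist.

## Numerical and interface choices

- Text formats throughout: TSV matrices (gene ids first column, header
  row), two-column sample sheet, GMT gene sets, two-column edge lists;
  readers tolerate blank lines and `#` comments; matrices serialize at 6
  significant digits (the documented round-trip precision).
- The pipeline (`run_pipeline` / `hetex run`) chains the stages, writes
  every stage's table plus `summary.json` and the resolved configuration,
  and is byte-deterministic for a fixed configuration and seed (the
  `force` overwrite flag is excluded from the config echo for that reason).
  Stage failures propagate with the stage name prefixed.
- All replicate columns are treated as biological replicates.
- Default problem sizes in tests and the acceptance script (20,000 genes
  for recovery, 2,000 for calibration checks, 500 random tables for letter
  display properties) are chosen to give stable Monte-Carlo estimates at
  interactive runtimes.

## Known limitations

- No count-model DEG test ships by default; very low counts rely on the
  pseudocount and the moderation prior.
- The additive/dominant labels depend on the configurable MPH band and
  significance gates; only the transgressive classes are standard.
- Median-of-ratios factors assume a core of genes with stable expression
  across groups; designs where most genes change would defeat any
  reference-based normalization.
- Correlations pool all samples across groups; with strong group structure
  r mixes between- and within-group association (the within-group option is
  simply subsetting the trait table before the call).
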