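# hetex

Heterosis expression-pattern analysis for two-parent/hybrid transcriptome
designs.

## The problem

Crossbred animals often outperform both purebred parents — hybrid vigor, or
*heterosis*. In a typical design (e.g., two pig breeds and their cross, five
muscle-transcriptome replicates per group), the question is which genes are
expressed **outside the parental range** in the hybrid, because such
transgressive (over-/under-dominant) expression is the transcriptional
signature of non-additive inheritance and points to candidate genes behind
improved traits such as tenderness, meat color and intramuscular fat.

`hetex` takes a gene × sample count (or FPKM) matrix with samples labelled
`parentA`, `parentB`, `hybrid`, and computes the standard heterosis
statistics per gene:

- mid-parent value **MPV** = (P̄₁ + P̄₂) / 2
- mid-parent heterosis **MPH** = 100 · (H̄ − MPV) / MPV
- best-parent heterosis **BPH** = 100 · (H̄ − max(P̄₁, P̄₂)) / max(P̄₁, P̄₂)

and classifies each gene from two hybrid-vs-parent differential-expression
contrasts:

| pattern | rule |
| --- | --- |
| transgressive_up (overdominant) | significantly up vs **both** parents |
| transgressive_down (underdominant) | significantly down vs both parents |
| dominant_like | significant vs exactly one parent |
| additive_like | significant vs neither, \|MPH\| within a small band |

Hybrid-vigor **candidates** are transgressive-up genes with BPH > 0, ranked
by BPH. Around the core classifier the package provides the usual downstream
steps: moderated-t differential expression with Benjamini–Hochberg
adjustment, Tukey HSD trait comparisons with compact letter displays,
gene–trait Pearson correlations with significance stars, degree-based
hub-gene ranking on a user-supplied interaction network, and hypergeometric
gene-set enrichment against GMT collections. A seeded negative-binomial
simulator with known per-gene inheritance modes makes the whole pipeline
testable end to end.

## Worked example

```python
from hetex import (PatternCallConfig, SimConfig, classify_patterns,
                   compute_heterosis_stats, filter_expressed, normalize_fpkm,
                   run_contrast, select_candidates, simulate_expression)

counts, truth = simulate_expression(SimConfig(n_genes=5000, seed=42))
expr = filter_expressed(normalize_fpkm(counts, library_size="median_ratio"))

config = PatternCallConfig()
deg_a = run_contrast(expr, "parentA", "hybrid", config.thresholds)
deg_b = run_contrast(expr, "parentB", "hybrid", config.thresholds)
classified = classify_patterns(compute_heterosis_stats(expr), deg_a, deg_b, config)
```

This prints (see `examples/01_simulate_and_classify.py`):

```
pattern counts:
dominant_like         1743
additive_like         1526
transgressive_up       884
transgressive_down     481
unclassified           366
overdominant recall: 0.867
underdominant recall: 0.902
candidates (transgressive up, BPH > 0): 884
top candidate G01317: BPH +276.3%, MPH +366.5%
```

The simulation planted 20% overdominant and 10% underdominant genes at a
2-fold transgressive effect; the classifier recovers ~87% and ~90% of them,
and every recovered overdominant gene with positive BPH lands on the
candidate list, led by the gene whose hybrid expression most exceeds its
better parent.

The other scripts in `examples/` each demonstrate one capability:
differential expression, trait Tukey/correlation statistics, hub genes and
enrichment, and the one-call pipeline (`run_pipeline`, also available from
the shell as `hetex run --config cfg.yaml`).

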