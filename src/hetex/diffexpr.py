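"""Per-gene differential expression between design groups.

Each contrast compares the replicate abundances of a test group against a
reference group on the log2(abundance + pseudocount) scale.  The per-gene
statistic is a two-sample t-test; by default :func:`run_contrast` moderates
the per-gene variances toward an empirical-Bayes prior fitted across all
genes — the standard remedy for unstable variance estimates at ~5 replicates
per group — while :func:`test_gene` provides the plain per-gene Welch test
as the isolated single-gene contract (``run_contrast(..., moderation=False)``
matches it exactly).  Fold change is reported as
``log2((mean_test + c) / (mean_ref + c))`` on the abundance scale,
Benjamini–Hochberg adjustment is applied across all tested genes, and
significance calls follow configurable thresholds (defaults: raw p < 0.05
and |log2FC| > 1).

Degenerate genes are handled explicitly rather than left to NaN arithmetic:
if both groups are constant and equal the p-value is 1; if both are constant
but unequal, the p-value falls back to an exact two-sided rank test
(Mann–Whitney U), which is well-defined for constant, tied-free groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import UsageError
from .io import ABUNDANCE, ExpressionMatrix, GROUPS

UP = "up_in_test"
DOWN = "down_in_test"
NS = "not_significant"


@dataclass(frozen=True)
class DEGThresholds:
    """Significance thresholds for calling differentially expressed genes.

    ``use_adjusted`` switches the p gate from raw to BH-adjusted p-values;
    ``lfc_cutoff`` is a strict bound (a gene must exceed it).
    """

    p_cutoff: float = 0.05
    lfc_cutoff: float = 1.0
    use_adjusted: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.p_cutoff < 1:
            raise UsageError("p_cutoff must be in (0, 1)")
        if self.lfc_cutoff < 0:
            raise UsageError("lfc_cutoff must be >= 0")


def test_gene(values_ref, values_test, pseudocount: float = 1.0) -> tuple[float, float]:
    """Welch's t-test and fold change for a single gene.

    Parameters are replicate abundance vectors (>= 2 each).  Returns
    ``(log2fc, p_value)`` with log2fc of the test group over the reference.
    """
    ref = np.asarray(values_ref, dtype=float)
    test = np.asarray(values_test, dtype=float)
    if ref.size < 2 or test.size < 2:
        raise UsageError("each group needs at least 2 replicates")
    c = pseudocount
    log2fc = float(np.log2((test.mean() + c) / (ref.mean() + c)))
    p = _welch_p(np.log2(ref + c), np.log2(test + c))
    return log2fc, float(p)


def _welch_p(log_ref: np.ndarray, log_test: np.ndarray) -> float:
    """Two-sided Welch p on log values with the documented zero-variance rule."""
    if np.ptp(log_ref) == 0 and np.ptp(log_test) == 0:
        if log_ref[0] == log_test[0]:
            return 1.0
        return float(stats.mannwhitneyu(log_test, log_ref,
                                        alternative="two-sided", method="exact").pvalue)
    return float(stats.ttest_ind(log_test, log_ref, equal_var=False).pvalue)


def _welch_p_matrix(lref: np.ndarray, ltst: np.ndarray) -> np.ndarray:
    """Vectorized Welch p with the zero-variance rule applied per gene."""
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.ttest_ind(ltst, lref, axis=1, equal_var=False).pvalue
    p = np.asarray(p, dtype=float)
    # Zero variance on both sides defeats the t statistic; patch per the rule.
    flat = (np.ptp(lref, axis=1) == 0) & (np.ptp(ltst, axis=1) == 0)
    for i in np.flatnonzero(flat):
        p[i] = _welch_p(lref[i], ltst[i])
    return p


def _squeeze_var(s2: np.ndarray, df: int) -> tuple[np.ndarray, float]:
    """Empirical-Bayes variance moderation (scaled inverse-chi-square prior).

    Fits the prior degrees of freedom d0 and scale s0^2 to the observed
    per-gene pooled variances by the method of moments on log(s^2), then
    returns the posterior variances (d0*s0^2 + df*s^2) / (d0 + df) and d0.
    d0 = inf collapses every variance to the common prior scale.
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    var_e = e.var(ddof=1) - float(special.polygamma(1, df / 2))
    if var_e <= 0:
        s02 = float(np.exp(e.mean()))
        return np.full_like(s2, s02), np.inf
    # invert the trigamma function by Newton's method (always converges here)
    x = 0.5 + 1.0 / var_e
    for _ in range(60):
        step = (float(special.polygamma(1, x)) - var_e) / float(special.polygamma(2, x))
        x -= step
        if abs(step) < 1e-10 * x:
            break
    d0 = 2.0 * x
    s02 = float(np.exp(e.mean() + special.digamma(x) - np.log(x)))
    return (d0 * s02 + df * s2) / (d0 + df), d0


def _moderated_p_matrix(lref: np.ndarray, ltst: np.ndarray) -> np.ndarray | None:
    """Moderated-t p-values pooling variance information across genes.

    The statistic is the ordinary pooled-variance t on the log values, with
    the per-gene variance replaced by its empirical-Bayes posterior and the
    degrees of freedom augmented by the prior's.  Returns None when fewer
    than 10 genes carry variance information (tiny toy inputs), in which
    case the caller falls back to per-gene Welch tests.
    """
    n1, n2 = lref.shape[1], ltst.shape[1]
    df = n1 + n2 - 2
    s2 = (
        ((lref - lref.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        + ((ltst - ltst.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ) / df
    if (s2 > 0).sum() < 10:
        return None
    s2_post, d0 = _squeeze_var(s2, df)
    diff = ltst.mean(axis=1) - lref.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    df_total = df + d0 if np.isfinite(d0) else 1e9
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # diff == 0 gives t == 0 even if s2_post were 0; guard any residual NaN
    p = np.where(np.isnan(p), 1.0, p)
    return p


def apply_calls(records: pd.DataFrame, thresholds: DEGThresholds) -> pd.DataFrame:
    """Return a copy of a DEG table with the ``call`` column recomputed."""
    out = records.copy()
    p = out["p_adjusted"] if thresholds.use_adjusted else out["p_value"]
    sig = p < thresholds.p_cutoff
    out["call"] = NS
    out.loc[sig & (out["log2fc"] > thresholds.lfc_cutoff), "call"] = UP
    out.loc[sig & (out["log2fc"] < -thresholds.lfc_cutoff), "call"] = DOWN
    return out


def run_contrast(
    expr: ExpressionMatrix,
    reference: str,
    test: str,
    thresholds: DEGThresholds = DEGThresholds(),
    pseudocount: float = 1.0,
    moderation: bool = True,
) -> pd.DataFrame:
    """Test every gene for differential expression test-vs-reference.

    By default the p-value is a variance-moderated t on the log2 values:
    per-gene variances are shrunk toward an empirical-Bayes prior fitted
    across all genes, the standard remedy for noisy variance estimates at
    ~5 replicates.  ``moderation=False`` uses an independent Welch t per
    gene, matching :func:`test_gene` exactly.

    Returns a DataFrame indexed by gene id with columns ``reference``,
    ``test``, ``log2fc``, ``p_value``, ``p_adjusted`` (Benjamini–Hochberg
    over all tested genes) and ``call``.
    """
    if expr.scale != ABUNDANCE:
        raise UsageError(f"run_contrast expects abundance values, got '{expr.scale}'")
    for g in (reference, test):
        if g not in GROUPS:
            raise UsageError(f"unknown group '{g}'")
    ref = expr.group_values(reference).to_numpy()
    tst = expr.group_values(test).to_numpy()
    if ref.shape[1] < 2 or tst.shape[1] < 2:
        raise UsageError("each group needs at least 2 replicates")
    c = pseudocount
    log2fc = np.log2((tst.mean(axis=1) + c) / (ref.mean(axis=1) + c))
    lref = np.log2(ref + c)
    ltst = np.log2(tst + c)
    p = _moderated_p_matrix(lref, ltst) if moderation else None
    if p is None:
        p = _welch_p_matrix(lref, ltst)
    p_adj = multipletests(p, method="fdr_bh")[1]
    records = pd.DataFrame(
        {
            "reference": reference,
            "test": test,
            "log2fc": log2fc,
            "p_value": p,
            "p_adjusted": p_adj,
        },
        index=expr.values.index,
    )
    return apply_calls(records, thresholds)


def filter_expressed(expr: ExpressionMatrix, min_mean_abundance: float = 1.0) -> ExpressionMatrix:
    """Drop genes whose mean abundance over all samples is below the floor."""
    if expr.scale != ABUNDANCE:
        raise UsageError(f"filter_expressed expects abundance values, got '{expr.scale}'")
    keep = expr.values.mean(axis=1) >= min_mean_abundance
    logging.getLogger(__name__).info(
        "filter_expressed: kept %d / %d genes (min mean %.3g)",
        int(keep.sum()), len(keep), min_mean_abundance,
    )
    return ExpressionMatrix(expr.values.loc[keep], expr.sample_groups, expr.scale)
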