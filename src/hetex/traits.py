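"""Breed-level trait comparisons and gene-trait correlations.

Two capabilities:

* All-pairs Tukey HSD on a one-way layout (the three breed groups), with a
  compact letter display (CLD): groups sharing a letter are not significantly
  different at the chosen alpha.  Pairwise p-values come from the studentized
  range distribution on the pooled ANOVA error (Tukey–Kramer for unbalanced
  groups, via ``scipy.stats.tukey_hsd``); the letters are assigned by the
  insert-and-absorb algorithm.

* Pearson correlation between gene expression and numeric traits over the
  samples shared by both tables, with two-sided p-values and significance
  stars at p < 0.05 (*), < 0.01 (**), < 0.001 (***).  The expression side
  uses log2 abundance by default, which stabilizes Pearson r against
  high-expression outliers.  Constant vectors yield an undefined (NaN) r
  that is flagged, never fabricated.  No multiple-testing correction is
  applied across the matrix by default (per-cell stars); BH is available as
  an option.

Trait tables are DataFrames indexed by sample id with a ``group`` column and
one numeric column per trait.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import UsageError
from .io import ABUNDANCE, LOG2_ABUNDANCE, ExpressionMatrix

STAR_THRESHOLDS = (0.05, 0.01, 0.001)


def stars_for(p: float, thresholds: Sequence[float] = STAR_THRESHOLDS) -> str:
    """Significance stars for a p-value: one star per threshold crossed."""
    if np.isnan(p):
        return ""
    return "*" * sum(p < t for t in sorted(thresholds, reverse=True))


@dataclass
class TukeyResult:
    """All-pairs Tukey HSD outcome for one trait."""

    trait_name: str | None
    means: dict[str, float]
    n_obs: dict[str, int]
    p_values: dict[tuple[str, str], float]
    alpha: float
    letters: dict[str, str]


def compact_letter_display(
    items: Sequence[str],
    significant_pairs: Sequence[tuple[str, str]],
    order: Sequence[str] | None = None,
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts from a single letter column containing every item; each
    significant pair splits any column containing both, and columns that
    become subsets of another are absorbed.  Guarantees: significantly
    different items never share a letter, and items not separated by any
    significant pair always share at least one.

    ``order`` fixes which column gets 'a' (conventionally, means descending).
    """
    items = list(items)
    if order is None:
        order = items
    rank = {it: i for i, it in enumerate(order)}
    cols: list[set[str]] = [set(items)]
    for i, j in significant_pairs:
        split: list[set[str]] = []
        for col in cols:
            if i in col and j in col:
                split.append(col - {i})
                split.append(col - {j})
            else:
                split.append(col)
        # absorb: keep only maximal columns (dedup included)
        cols = []
        for c in sorted(split, key=len, reverse=True):
            if c and not any(c <= kept for kept in cols):
                cols.append(c)
    cols.sort(key=lambda c: min(rank[it] for it in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {it: "" for it in items}
    for letter, col in zip(alphabet, cols):
        for it in col:
            letters[it] += letter
    return letters


def tukey_hsd(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    trait_name: str | None = None,
) -> TukeyResult:
    """All-pairs Tukey HSD over a one-way layout with CLD letters.

    ``groups`` maps group name -> observation vector (>= 2 finite values
    each; >= 2 groups).  Letters are ordered so that 'a' belongs to the
    group with the largest mean.
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(names) < 2:
        raise UsageError("tukey_hsd needs at least 2 groups")
    for g, a in zip(names, arrays):
        if a.size < 2:
            raise UsageError(f"group '{g}' has fewer than 2 observations")
        if not np.isfinite(a).all():
            raise UsageError(f"group '{g}' contains non-finite values")
    res = stats.tukey_hsd(*arrays)
    p_values = {
        (names[i], names[j]): float(res.pvalue[i, j])
        for i, j in combinations(range(len(names)), 2)
    }
    means = {g: float(a.mean()) for g, a in zip(names, arrays)}
    by_mean = sorted(names, key=lambda g: -means[g])
    sig = [pair for pair, p in p_values.items() if p < alpha]
    letters = compact_letter_display(names, sig, order=by_mean)
    return TukeyResult(
        trait_name=trait_name,
        means=means,
        n_obs={g: int(a.size) for g, a in zip(names, arrays)},
        p_values=p_values,
        alpha=alpha,
        letters=letters,
    )


def summarize_traits(traits: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-group trait means annotated with Tukey CLD letters.

    Long-form output: one row per (trait, group) with columns ``trait``,
    ``group``, ``n``, ``mean``, ``letter``.  Missing values are dropped per
    trait before testing.
    """
    if "group" not in traits.columns:
        raise UsageError("trait table must have a 'group' column")
    trait_cols = [c for c in traits.columns if c != "group"]
    rows = []
    for trait in trait_cols:
        sub = traits[["group", trait]].dropna()
        groups = {g: sub.loc[sub["group"] == g, trait].to_numpy()
                  for g in sub["group"].unique()}
        result = tukey_hsd(groups, alpha=alpha, trait_name=trait)
        for g in groups:
            rows.append({"trait": trait, "group": g, "n": result.n_obs[g],
                         "mean": result.means[g], "letter": result.letters[g]})
    return pd.DataFrame(rows)


def correlate_genes_traits(
    expr: ExpressionMatrix,
    traits: pd.DataFrame,
    genes: Sequence[str] | None = None,
    use_log: bool = True,
    pseudocount: float = 1.0,
    star_thresholds: Sequence[float] = STAR_THRESHOLDS,
    adjust: bool = False,
) -> pd.DataFrame:
    """Pearson r, two-sided p and stars for every gene x trait pair.

    Correlations run over the samples shared by the expression matrix and
    the trait table (>= 3 required).  Long-form output with columns
    ``gene_id``, ``trait``, ``r``, ``p_value``, ``stars``, ``defined``.
    With ``adjust=True`` a BH-adjusted p feeds the stars instead.
    """
    if expr.scale not in (ABUNDANCE, LOG2_ABUNDANCE):
        raise UsageError("correlate_genes_traits expects abundance or log2 values")
    shared = [s for s in expr.sample_ids if s in traits.index]
    if len(shared) < 3:
        raise UsageError(f"only {len(shared)} shared sample(s); need >= 3")
    if genes is None:
        genes = expr.gene_ids
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise LookupError(f"genes absent from expression matrix: {missing[:5]}")
    x = expr.values.loc[list(genes), shared]
    if use_log and expr.scale == ABUNDANCE:
        x = np.log2(x + pseudocount)
    trait_cols = [c for c in traits.columns if c != "group"]
    rows = []
    for gene in genes:
        gv = x.loc[gene].to_numpy(dtype=float)
        for trait in trait_cols:
            tv = traits.loc[shared, trait].to_numpy(dtype=float)
            ok = np.isfinite(gv) & np.isfinite(tv)
            if ok.sum() < 3 or np.ptp(gv[ok]) == 0 or np.ptp(tv[ok]) == 0:
                rows.append({"gene_id": gene, "trait": trait, "r": np.nan,
                             "p_value": np.nan, "defined": False})
                continue
            r, p = stats.pearsonr(gv[ok], tv[ok])
            rows.append({"gene_id": gene, "trait": trait, "r": float(r),
                         "p_value": float(p), "defined": True})
    out = pd.DataFrame(rows)
    p_for_stars = out["p_value"].copy()
    if adjust and out["defined"].any():
        mask = out["defined"].to_numpy()
        adj = np.full(len(out), np.nan)
        adj[mask] = multipletests(out.loc[mask, "p_value"], method="fdr_bh")[1]
        out["p_adjusted"] = adj
        p_for_stars = out["p_adjusted"]
    out["stars"] = [stars_for(p, star_thresholds) for p in p_for_stars]
    return out


def correlation_heatmap(corr: pd.DataFrame, path: str) -> None:
    """Optional seaborn heatmap of a long-form correlation table.

    Purely presentational; the numbers are always available as text via
    the returned tables, so nothing downstream ever reads pixels.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    wide_r = corr.pivot(index="gene_id", columns="trait", values="r")
    wide_s = corr.pivot(index="gene_id", columns="trait", values="stars")
    fig, ax = plt.subplots(figsize=(1.2 * len(wide_r.columns) + 2,
                                    0.5 * len(wide_r) + 2))
    sns.heatmap(wide_r, annot=wide_s, fmt="", cmap="RdBu_r", center=0,
                vmin=-1, vmax=1, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
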