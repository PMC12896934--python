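"""Mid-parent / best-parent heterosis statistics and expression-pattern calls.

For each gene, group mean abundances over the two parental lines and their
hybrid yield:

* MPV, the mid-parent value: (mean_parentA + mean_parentB) / 2
* MPH, mid-parent heterosis:  100 * (mean_hybrid - MPV) / MPV
* BPH, best-parent heterosis: 100 * (mean_hybrid - high_parent) / high_parent

where ``high_parent`` is the parent with the larger mean.  MPH >= BPH holds
for every gene with defined values, since the high-parent mean is never below
the MPV.  Genes whose MPV falls below a floor (default 1 abundance unit) get
undefined MPH/BPH — the ratios are numerically meaningless near zero — and
are excluded from pattern classification but kept in the output.

Pattern classification is driven by the significance calls of two
hybrid-vs-parent contrasts:

* ``transgressive_up``   — significantly up in the hybrid vs *both* parents
  (overdominant expression)
* ``transgressive_down`` — significantly down vs both parents (underdominant)
* ``dominant_like``      — significant vs exactly one parent
* ``additive_like``      — significant vs neither and |MPH| within a small
  band (default 20%) around the mid-parent expectation
* ``unclassified``       — significant vs neither, but outside that band

Only the two transgressive classes are standard; the dominant/additive
labels are a convenience extension and are flagged as such in the docs.
Hybrid-vigor candidates are transgressive_up genes with BPH strictly > 0,
ranked by descending BPH.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import DOWN, UP, DEGThresholds
from .errors import UsageError
from .io import ABUNDANCE, ExpressionMatrix

logger = logging.getLogger(__name__)

TRANSGRESSIVE_UP = "transgressive_up"
TRANSGRESSIVE_DOWN = "transgressive_down"
ADDITIVE_LIKE = "additive_like"
DOMINANT_LIKE = "dominant_like"
UNCLASSIFIED = "unclassified"
#: Placeholder pattern for genes excluded from classification (MPV < floor).
UNDEFINED = "NA"


@dataclass(frozen=True)
class PatternCallConfig:
    """Configuration of the pattern classifier.

    ``thresholds`` are the DEG thresholds used when (re)deriving the
    significance calls feeding the classifier.  The default gates on the
    p-value only (lfc_cutoff = 0): the transgressive categories are defined
    by *significant* up/down-regulation versus both parents, while the
    |log2FC| > 1 gate belongs to DEG-list identification and would blind the
    classifier to real effects at or below a 2-fold boundary.
    """

    thresholds: DEGThresholds = field(
        default_factory=lambda: DEGThresholds(p_cutoff=0.05, lfc_cutoff=0.0)
    )
    min_mpv: float = 1.0
    additive_band: float = 20.0

    def __post_init__(self) -> None:
        if not self.min_mpv > 0:
            raise UsageError("min_mpv must be positive")
        if self.additive_band < 0:
            raise UsageError("additive_band must be >= 0")


def compute_heterosis_stats(expr: ExpressionMatrix, min_mpv: float = 1.0) -> pd.DataFrame:
    """Per-gene group means, MPV, high parent, MPH% and BPH%.

    Returns a DataFrame indexed by gene id with columns ``mean_parentA``,
    ``mean_parentB``, ``mean_hybrid``, ``mpv``, ``high_parent``, ``mph_pct``,
    ``bph_pct``.  Genes with MPV below ``min_mpv`` carry NaN MPH/BPH; their
    count is logged, never silently dropped.
    """
    if expr.scale != ABUNDANCE:
        raise UsageError(f"compute_heterosis_stats expects abundance, got '{expr.scale}'")
    means = expr.group_means()
    ma = means["parentA"].to_numpy()
    mb = means["parentB"].to_numpy()
    mh = means["hybrid"].to_numpy()
    mpv = (ma + mb) / 2.0
    # Ties go to parentA by convention; BPH is unaffected since means are equal.
    high_is_a = ma >= mb
    n_ties = int((ma == mb).sum())
    if n_ties:
        logger.info("%d gene(s) with equal parental means; high_parent set to parentA", n_ties)
    hp_mean = np.where(high_is_a, ma, mb)
    defined = mpv >= min_mpv
    n_undef = int((~defined).sum())
    if n_undef:
        logger.info("%d gene(s) with MPV < %.3g: MPH/BPH undefined", n_undef, min_mpv)
    with np.errstate(invalid="ignore", divide="ignore"):
        mph = np.where(defined, 100.0 * (mh - mpv) / mpv, np.nan)
        bph = np.where(defined, 100.0 * (mh - hp_mean) / hp_mean, np.nan)
    return pd.DataFrame(
        {
            "mean_parentA": ma,
            "mean_parentB": mb,
            "mean_hybrid": mh,
            "mpv": mpv,
            "high_parent": np.where(high_is_a, "parentA", "parentB"),
            "mph_pct": mph,
            "bph_pct": bph,
        },
        index=means.index,
    )


def _check_contrast(records: pd.DataFrame, expected_ref: str, genes: pd.Index) -> None:
    if (records["test"] != "hybrid").any():
        raise UsageError("DEG contrast must have the hybrid as test group")
    refs = set(records["reference"].unique())
    if refs != {expected_ref}:
        raise UsageError(f"expected contrast vs {expected_ref}, got reference(s) {sorted(refs)}")
    if set(records.index) != set(genes):
        raise UsageError("DEG records do not cover the same gene universe as the heterosis table")


def classify_patterns(
    records: pd.DataFrame,
    deg_vs_parentA: pd.DataFrame,
    deg_vs_parentB: pd.DataFrame,
    config: PatternCallConfig = PatternCallConfig(),
) -> pd.DataFrame:
    """Assign a heterosis expression pattern to every gene with defined MPH.

    ``records`` is the output of :func:`compute_heterosis_stats`; the two DEG
    tables must come from hybrid-vs-parentA and hybrid-vs-parentB contrasts
    over the same gene universe (their ``call`` columns are the single source
    of significance).  Adds ``pattern`` and ``candidate`` columns.
    """
    _check_contrast(deg_vs_parentA, "parentA", records.index)
    _check_contrast(deg_vs_parentB, "parentB", records.index)
    call_a = deg_vs_parentA["call"].reindex(records.index)
    call_b = deg_vs_parentB["call"].reindex(records.index)

    defined = records["mph_pct"].notna().to_numpy()
    up_both = (call_a == UP).to_numpy() & (call_b == UP).to_numpy()
    down_both = (call_a == DOWN).to_numpy() & (call_b == DOWN).to_numpy()
    sig_a = (call_a != "not_significant").to_numpy()
    sig_b = (call_b != "not_significant").to_numpy()
    sig_one = sig_a ^ sig_b
    sig_none = ~sig_a & ~sig_b
    additive = sig_none & (np.abs(records["mph_pct"].to_numpy()) <= config.additive_band)

    pattern = np.full(len(records), UNCLASSIFIED, dtype=object)
    pattern[up_both] = TRANSGRESSIVE_UP
    pattern[down_both] = TRANSGRESSIVE_DOWN
    # "significant vs one parent, in discordant directions" is rare but
    # logically possible (up vs one, down vs the other): kept unclassified.
    pattern[sig_one & ~(up_both | down_both)] = DOMINANT_LIKE
    pattern[additive] = ADDITIVE_LIKE
    pattern[~defined] = UNDEFINED

    out = records.copy()
    out["pattern"] = pattern
    out["candidate"] = (out["pattern"] == TRANSGRESSIVE_UP) & (out["bph_pct"] > 0)
    return out


def select_candidates(records: pd.DataFrame) -> list[str]:
    """Hybrid-vigor candidates: transgressive_up genes with BPH > 0.

    Sorted by descending BPH; gene id breaks ties for a stable order.
    """
    if "pattern" not in records.columns:
        raise UsageError("patterns not set; run classify_patterns first")
    cand = records[records["candidate"]]
    order = sorted(zip(-cand["bph_pct"], cand.index))
    return [g for _, g in order]


def intersect_upregulated(
    deg_vs_parentA: pd.DataFrame, deg_vs_parentB: pd.DataFrame
) -> list[str]:
    """Genes up-regulated in the hybrid versus *both* parents.

    By construction this equals the transgressive_up set of
    :func:`classify_patterns` (restricted to genes with defined MPH); the
    pipeline asserts that equivalence as an internal cross-check.
    """
    if set(deg_vs_parentA.index) != set(deg_vs_parentB.index):
        raise UsageError("contrasts cover different gene universes")
    up_a = set(deg_vs_parentA.index[deg_vs_parentA["call"] == UP])
    up_b = set(deg_vs_parentB.index[deg_vs_parentB["call"] == UP])
    return sorted(up_a & up_b)
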