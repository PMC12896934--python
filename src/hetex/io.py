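"""Containers and text-format I/O for expression data, gene sets and networks.

The central container is :class:`ExpressionMatrix`: a genes x samples table
with every sample assigned to one of the three design groups (``parentA``,
``parentB``, ``hybrid``) and a scale tag recording whether the values are raw
counts, a normalized abundance (FPKM-like), or log2 abundance.

All file formats are plain text: TSV matrices with a header row and gene ids
in the first column, a two-column sample sheet, GMT gene-set collections and
two-column edge lists.  Readers tolerate blank lines and ``#`` comments.
Matrices are written with 6 significant digits, which is the documented
round-trip precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, UsageError

logger = logging.getLogger(__name__)

#: The three design groups, in canonical order.
GROUPS = ("parentA", "parentB", "hybrid")

COUNTS = "counts"
ABUNDANCE = "abundance"
LOG2_ABUNDANCE = "log2_abundance"
SCALES = (COUNTS, ABUNDANCE, LOG2_ABUNDANCE)

#: Text serialization precision (significant digits) for matrices.
FLOAT_FORMAT = "%.6g"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with group labels and a scale tag.

    Parameters
    ----------
    values
        DataFrame with gene ids as index and sample ids as columns.
    sample_groups
        Mapping sample id -> group; must cover exactly the matrix columns
        and every one of the three groups must be non-empty.
    scale
        One of ``counts``, ``abundance``, ``log2_abundance``.  Values must
        be finite, and non-negative on the counts/abundance scales.
    """

    values: pd.DataFrame
    sample_groups: Mapping[str, str]
    scale: str = COUNTS

    def __post_init__(self) -> None:
        vals = self.values
        if vals.index.has_duplicates:
            dupes = sorted(set(vals.index[vals.index.duplicated()]))
            raise FormatError(f"duplicate gene ids: {dupes}")
        if vals.columns.has_duplicates:
            dupes = sorted(set(vals.columns[vals.columns.duplicated()]))
            raise FormatError(f"duplicate sample ids: {dupes}")
        groups = dict(self.sample_groups)
        unassigned = [s for s in vals.columns if s not in groups]
        if unassigned:
            raise FormatError(f"samples not assigned to any group: {unassigned}")
        orphans = [s for s in groups if s not in vals.columns]
        if orphans:
            raise FormatError(f"samples in sheet but absent from matrix: {orphans}")
        bad = sorted({g for g in groups.values() if g not in GROUPS})
        if bad:
            raise FormatError(f"unknown group labels {bad}; expected one of {GROUPS}")
        for g in GROUPS:
            if g not in groups.values():
                raise FormatError(f"group '{g}' has no samples")
        if self.scale not in SCALES:
            raise UsageError(f"unknown scale '{self.scale}'; expected one of {SCALES}")
        arr = vals.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise FormatError("expression values must be finite")
        if self.scale in (COUNTS, ABUNDANCE) and (arr < 0).any():
            raise FormatError(f"negative values are not allowed on the {self.scale} scale")
        self.values = vals.astype(float)
        self.values.index.name = "gene_id"
        self.sample_groups = groups

    # -- convenience accessors -------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise UsageError(f"unknown group '{group}'")
        return [s for s in self.values.columns if self.sample_groups[s] == group]

    def group_values(self, group: str) -> pd.DataFrame:
        """Sub-matrix restricted to one group's samples."""
        return self.values[self.samples_in(group)]

    def group_means(self) -> pd.DataFrame:
        """Per-gene mean per group; columns ordered parentA, parentB, hybrid."""
        return pd.DataFrame(
            {g: self.group_values(g).mean(axis=1) for g in GROUPS}
        )

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.sample_groups, self.scale)

    # -- serialization ---------------------------------------------------

    def write(self, matrix_path: str | Path, sample_sheet_path: str | Path | None = None) -> None:
        self.values.to_csv(matrix_path, sep="\t", float_format=FLOAT_FORMAT)
        if sample_sheet_path is not None:
            sheet = pd.DataFrame(
                {"sample_id": self.sample_ids,
                 "group": [self.sample_groups[s] for s in self.sample_ids]}
            )
            sheet.to_csv(sample_sheet_path, sep="\t", index=False)


def read_expression(
    matrix_path: str | Path,
    sample_sheet_path: str | Path,
    scale: str = COUNTS,
) -> ExpressionMatrix:
    """Read a TSV expression matrix plus its sample sheet and validate both.

    The sample sheet must have columns ``sample_id`` and ``group`` and cover
    exactly the matrix columns; any mismatch in either direction is a
    :class:`FormatError` naming the offending samples.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    sheet = pd.read_csv(sample_sheet_path, sep="\t", comment="#")
    for col in ("sample_id", "group"):
        if col not in sheet.columns:
            raise FormatError(f"sample sheet is missing column '{col}'")
    groups = dict(zip(sheet["sample_id"].astype(str), sheet["group"].astype(str)))
    return ExpressionMatrix(values, groups, scale)


def read_gene_lengths(path: str | Path) -> dict[str, float]:
    """Two-column TSV (gene id, length in bases) -> mapping."""
    table = pd.read_csv(path, sep="\t", header=None, comment="#",
                        names=["gene_id", "length"])
    lengths = dict(zip(table["gene_id"].astype(str), table["length"].astype(float)))
    bad = [g for g, l in lengths.items() if not l > 0]
    if bad:
        raise FormatError(f"non-positive gene lengths for: {bad[:5]}")
    return lengths


def median_ratio_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors (geometric-mean reference).

    For each sample, the factor is the median over genes of
    ``count / geometric_mean_across_samples``, using only genes expressed in
    every sample.  Factors are rescaled to geometric mean 1.  Unlike the raw
    library total, this estimator is robust to composition shifts — a block
    of strongly up-regulated genes in one group inflates that group's totals
    and would otherwise depress every other gene's normalized abundance.
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if positive.sum() < 10:
        raise UsageError("too few genes expressed in every sample for median-ratio factors")
    log_arr = np.log(arr[positive])
    log_ref = log_arr.mean(axis=1)
    factors = np.exp(np.median(log_arr - log_ref[:, None], axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


def _refined_size_factors(expr: "ExpressionMatrix", stable_quantile: float = 0.3) -> pd.Series:
    """Two-pass median-ratio size factors anchored on group-stable genes.

    When a sizeable block of genes is genuinely up- or down-regulated in one
    group, even the median-of-ratios reference drifts with it.  The second
    pass re-estimates the factors using only the genes whose between-group
    variation (max pairwise |log2 ratio| of group means after pass one) falls
    in the lowest ``stable_quantile`` — a rank-based proxy for non-changing
    control genes that exists for any dataset.
    """
    sf = median_ratio_size_factors(expr.values)
    norm = expr.values.div(sf, axis=1)
    means = pd.DataFrame({g: norm[expr.samples_in(g)].mean(axis=1) for g in GROUPS})
    arr = means.to_numpy()
    usable = (arr > 0).all(axis=1) & (expr.values.to_numpy() > 0).all(axis=1)
    log_means = np.log2(arr[usable])
    spread = log_means.max(axis=1) - log_means.min(axis=1)
    cutoff = np.quantile(spread, stable_quantile)
    stable = np.zeros(len(expr.values), dtype=bool)
    stable[np.flatnonzero(usable)[spread <= cutoff]] = True
    if stable.sum() < 10:
        return sf
    log_arr = np.log(expr.values.to_numpy(dtype=float)[stable])
    log_ref = log_arr.mean(axis=1)
    factors = np.exp(np.median(log_arr - log_ref[:, None], axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=expr.values.columns)


def normalize_fpkm(
    expr: ExpressionMatrix,
    gene_lengths: Mapping[str, float] | None = None,
    library_size: str = "total",
) -> ExpressionMatrix:
    """Normalize raw counts to FPKM: count * 1e9 / (length * library total).

    If ``gene_lengths`` is omitted, every gene is treated as 1 kb, which makes
    the result a CPM ("counts per million").  All downstream statistics are
    per-gene, hence invariant to the per-gene length factor; a warning is
    logged so the scale tag is not over-interpreted.

    ``library_size`` selects the per-sample depth estimate: ``"total"`` (the
    textbook FPKM denominator, the sample's total counts) or
    ``"median_ratio"`` (composition-robust size factors scaled to the mean
    total, keeping FPKM-like units).
    """
    if expr.scale != COUNTS:
        raise UsageError(f"normalize_fpkm expects counts, got '{expr.scale}'")
    totals = expr.values.sum(axis=0)
    zero = [s for s in totals.index if totals[s] == 0]
    if zero:
        raise UsageError(f"zero library size for samples: {zero}")
    if library_size == "median_ratio":
        totals = _refined_size_factors(expr) * float(totals.mean())
    elif library_size != "total":
        raise UsageError(f"unknown library_size '{library_size}'")
    if gene_lengths is None:
        logger.warning("no gene lengths supplied; using 1 kb for every gene (CPM fallback)")
        lengths = np.full(len(expr.gene_ids), 1000.0)
    else:
        missing = [g for g in expr.gene_ids if g not in gene_lengths]
        if missing:
            raise LookupError(f"missing gene lengths for: {missing[:5]}"
                              + (" ..." if len(missing) > 5 else ""))
        lengths = np.array([float(gene_lengths[g]) for g in expr.gene_ids])
        if (lengths <= 0).any():
            raise FormatError("gene lengths must be positive")
    fpkm = expr.values.to_numpy() * 1e9 / (lengths[:, None] * totals.to_numpy()[None, :])
    out = pd.DataFrame(fpkm, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(out, expr.sample_groups, ABUNDANCE)


def log_transform(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(value + pseudocount) on the abundance scale."""
    if expr.scale != ABUNDANCE:
        raise UsageError(f"log_transform expects abundance, got '{expr.scale}'")
    if not pseudocount > 0:
        raise UsageError("pseudocount must be positive")
    out = np.log2(expr.values + pseudocount)
    return ExpressionMatrix(out, expr.sample_groups, LOG2_ABUNDANCE)


# ---------------------------------------------------------------------------
# Gene sets (GMT) and interaction edge lists


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT-style)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set '{name}' is empty")
            if len(set(members)) != len(members):
                # dedup preserving order
                seen: set[str] = set()
                self.sets[name] = [m for m in members if not (m in seen or seen.add(m))]

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line ``set_name<TAB>description<TAB>gene...``.

    Members are deduplicated preserving order.  Lines with fewer than three
    fields raise a :class:`FormatError` carrying the line number.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, desc = fields[0], fields[1]
            members = [g for g in fields[2:] if g]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set '{name}' has no members")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name '{name}'")
            seen: set[str] = set()
            sets[name] = [m for m in members if not (m in seen or seen.add(m))]
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


@dataclass
class EdgeList:
    """Undirected, deduplicated gene-gene interaction edges without self-loops.

    Pairs are stored in canonical (lexicographically sorted) orientation.
    """

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        canon: list[tuple[str, str]] = []
        seen: set[tuple[str, str]] = set()
        for a, b in self.pairs:
            if a == b:
                raise FormatError(f"self-loop on '{a}'")
            key = (a, b) if a <= b else (b, a)
            if key not in seen:
                seen.add(key)
                canon.append(key)
        self.pairs = canon

    @property
    def nodes(self) -> set[str]:
        return {g for pair in self.pairs for g in pair}

    def __len__(self) -> int:
        return len(self.pairs)


def read_edge_list(path: str | Path) -> EdgeList:
    """Read a two-column whitespace/tab edge file.

    Self-loops are dropped with a logged warning; duplicate edges (in either
    orientation) collapse to a single undirected edge.
    """
    pairs: list[tuple[str, str]] = []
    n_loops = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            a, b = fields
            if a == b:
                n_loops += 1
                continue
            pairs.append((a, b))
    if n_loops:
        logger.warning("dropped %d self-loop(s) while reading %s", n_loops, path)
    edges = EdgeList(pairs)
    logger.info("read %d undirected edges over %d genes from %s", len(edges), len(edges.nodes), path)
    return edges


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a results table as TSV with the shared float precision."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
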