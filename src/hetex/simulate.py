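"""Synthetic two-parent/hybrid expression datasets with known inheritance modes.

The generator emulates the design of a three-group muscle transcriptome
comparison — two purebred parental lines and their cross, five biological
replicates each, ~20,000 genes — without any sequencing-level detail.  Each
gene is assigned one generative inheritance mode:

* ``null``           — all three group means equal
* ``additive``       — hybrid mean = mid-parent value
* ``dominant_high``  — hybrid mean = the larger parental mean
* ``dominant_low``   — hybrid mean = the smaller parental mean
* ``overdominant``   — hybrid mean = effect_size x max(parents)  (transgressive up)
* ``underdominant``  — hybrid mean = min(parents) / effect_size  (transgressive down)

Baseline parental means are drawn log-uniform over [20, 2000] (an FPKM-scale
dynamic range); for non-null genes the second parent differs by a fixed fold
(default 2x, direction randomized).  Counts are negative-binomial around the
group mean scaled by a per-sample library factor, with variance
``mu + dispersion * mu**2`` (dispersion 0 recovers the Poisson limit).  The
per-gene truth (mode and the three means) is returned alongside the counts so
downstream classification can be scored against it.

Trait vectors are linear read-outs of designated driver genes: for sample
``s``, ``trait(s) = sum_g w_g * z_g(s) + N(0, noise_sd)`` where ``z_g`` is
the per-gene z-score of log2(CPM + 1) across samples.  With zero noise and a
single driver the trait is an exact affine image of that gene's log
expression, so its Pearson correlation with the driver is exactly +/-1.

Everything is driven by a single integer seed; identical configurations give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import COUNTS, ExpressionMatrix, GROUPS

MODES = ("additive", "dominant_high", "dominant_low",
         "overdominant", "underdominant", "null")

#: Study-scale default mode mix: 20% overdominant, 10% underdominant,
#: the rest split between additive/dominant and null genes.
DEFAULT_MODE_FRACTIONS: dict[str, float] = {
    "additive": 0.20,
    "dominant_high": 0.10,
    "dominant_low": 0.10,
    "overdominant": 0.20,
    "underdominant": 0.10,
    "null": 0.30,
}


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for :func:`simulate_expression`.

    Defaults are the study-scale conditions: 20,000 genes, 5 replicates per
    group, NB dispersion 0.1, a 2x transgressive effect, parents 2-fold
    apart, library-size factors uniform on (0.7, 1.3).
    """

    n_genes: int = 20_000
    n_reps_per_group: int = 5
    mode_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MODE_FRACTIONS)
    )
    effect_size: float = 2.0
    dispersion: float = 0.1
    libsize_range: tuple[float, float] = (0.7, 1.3)
    parent_fold: float = 2.0
    baseline_range: tuple[float, float] = (20.0, 2000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if self.n_reps_per_group < 2:
            raise ConfigError("n_reps_per_group must be >= 2")
        unknown = set(self.mode_fractions) - set(MODES)
        if unknown:
            raise ConfigError(f"unknown inheritance modes: {sorted(unknown)}")
        total = sum(self.mode_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"mode_fractions must sum to 1, got {total!r}")
        if any(f < 0 for f in self.mode_fractions.values()):
            raise ConfigError("mode_fractions must be non-negative")
        if not self.effect_size > 1:
            raise ConfigError("effect_size must be > 1")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise ConfigError("libsize_range must satisfy 0 < min <= max")
        if not self.parent_fold >= 1:
            raise ConfigError("parent_fold must be >= 1")


@dataclass(frozen=True)
class TraitSimSpec:
    """Trait -> [(driver gene, signed weight), ...] plus Gaussian noise SD."""

    driver_genes: Mapping[str, Sequence[tuple[str, float]]]
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not self.driver_genes:
            raise ConfigError("at least one trait must be specified")

    @property
    def trait_names(self) -> list[str]:
        return list(self.driver_genes)


def _allocate_modes(n_genes: int, fractions: Mapping[str, float]) -> list[str]:
    """Largest-remainder allocation: realized counts match fractions up to rounding."""
    quotas = {m: n_genes * fractions.get(m, 0.0) for m in MODES}
    counts = {m: int(np.floor(q)) for m, q in quotas.items()}
    short = n_genes - sum(counts.values())
    remainders = sorted(MODES, key=lambda m: (-(quotas[m] - counts[m]), m))
    for m in remainders[:short]:
        counts[m] += 1
    out: list[str] = []
    for m in MODES:
        out.extend([m] * counts[m])
    return out


def _hybrid_mean(mode: np.ndarray, mu_a: np.ndarray, mu_b: np.ndarray,
                 effect_size: float) -> np.ndarray:
    hi = np.maximum(mu_a, mu_b)
    lo = np.minimum(mu_a, mu_b)
    mid = (mu_a + mu_b) / 2.0
    out = np.empty_like(mu_a)
    out[mode == "null"] = mu_a[mode == "null"]
    out[mode == "additive"] = mid[mode == "additive"]
    out[mode == "dominant_high"] = hi[mode == "dominant_high"]
    out[mode == "dominant_low"] = lo[mode == "dominant_low"]
    out[mode == "overdominant"] = effect_size * hi[mode == "overdominant"]
    out[mode == "underdominant"] = lo[mode == "underdominant"] / effect_size
    return out


def simulate_expression(config: SimConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw a counts matrix and its per-gene truth table.

    Returns ``(ExpressionMatrix(counts), truth)`` where ``truth`` is indexed
    by gene id with columns ``mode``, ``mu_parentA``, ``mu_parentB``,
    ``mu_hybrid`` (the expected per-replicate means before library scaling).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]

    mode = np.array(_allocate_modes(n, config.mode_fractions), dtype=object)
    mode = mode[rng.permutation(n)]

    lo, hi = config.baseline_range
    mu_a = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    # Non-null genes: parent B differs by a fixed fold, direction randomized.
    direction = rng.choice([1.0, -1.0], size=n)
    mu_b = np.where(direction > 0, mu_a * config.parent_fold, mu_a / config.parent_fold)
    is_null = mode == "null"
    mu_b[is_null] = mu_a[is_null]
    mu_h = _hybrid_mean(mode, mu_a, mu_b, config.effect_size)

    truth = pd.DataFrame(
        {"mode": mode, "mu_parentA": mu_a, "mu_parentB": mu_b, "mu_hybrid": mu_h},
        index=pd.Index(gene_ids, name="gene_id"),
    )

    reps = config.n_reps_per_group
    sample_ids = [f"{g}_{r + 1}" for g in GROUPS for r in range(reps)]
    groups = {s: g for g in GROUPS for s in sample_ids if s.startswith(g)}
    lib = rng.uniform(config.libsize_range[0], config.libsize_range[1], size=3 * reps)

    mu_per_group = {"parentA": mu_a, "parentB": mu_b, "hybrid": mu_h}
    counts = np.empty((n, 3 * reps), dtype=np.int64)
    for j, s in enumerate(sample_ids):
        m = mu_per_group[groups[s]] * lib[j]
        if config.dispersion == 0:
            counts[:, j] = rng.poisson(m)
        else:
            r = 1.0 / config.dispersion
            counts[:, j] = rng.negative_binomial(r, r / (r + m))
    values = pd.DataFrame(counts, index=truth.index, columns=sample_ids)
    return ExpressionMatrix(values, groups, COUNTS), truth


def simulate_traits(
    expr: ExpressionMatrix, spec: TraitSimSpec, seed: int
) -> pd.DataFrame:
    """Trait table (samples x traits) linearly coupled to driver genes.

    Returns a DataFrame indexed by sample id with a ``group`` column followed
    by one numeric column per trait.
    """
    rng = np.random.default_rng(seed)
    for trait, drivers in spec.driver_genes.items():
        for gene, _ in drivers:
            if gene not in expr.values.index:
                raise LookupError(f"driver gene '{gene}' for trait '{trait}' "
                                  "is not in the expression matrix")
    vals = expr.values
    if expr.scale == COUNTS:
        vals = vals * 1e6 / vals.sum(axis=0)
    logv = np.log2(vals + 1.0)
    centered = logv.sub(logv.mean(axis=1), axis=0)
    sd = logv.std(axis=1, ddof=0).replace(0, 1.0)
    z = centered.div(sd, axis=0)

    out = pd.DataFrame(index=pd.Index(expr.sample_ids, name="sample_id"))
    out["group"] = [expr.sample_groups[s] for s in expr.sample_ids]
    for trait, drivers in spec.driver_genes.items():
        signal = np.zeros(len(expr.sample_ids))
        for gene, weight in drivers:
            signal = signal + weight * z.loc[gene].to_numpy()
        noise = rng.normal(0.0, spec.noise_sd, size=len(signal)) if spec.noise_sd > 0 else 0.0
        out[trait] = signal + noise
    return out
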