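"""End-to-end orchestration: data in, classified heterosis patterns and
downstream statistics out.

``run_pipeline`` chains the stages — simulate or read counts, FPKM/CPM
normalization, expression filter, the two hybrid-vs-parent DEG contrasts,
heterosis statistics and pattern classification, candidate selection, and
(when the corresponding inputs exist) hub genes, gene-set enrichment, trait
summaries and gene-trait correlations — writing every stage's table as TSV
plus a machine-readable ``summary.json`` and the resolved configuration.

Runs are deterministic: identical configuration and seed give byte-identical
output files.  Stage errors propagate with the stage name prefixed.
"""

from __future__ import annotations

import json
import logging
import time
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .diffexpr import (DOWN, UP, DEGThresholds, apply_calls, filter_expressed,
                       run_contrast)
from .errors import ConfigError, HetexError
from .heterosis import (TRANSGRESSIVE_DOWN, TRANSGRESSIVE_UP, PatternCallConfig,
                        classify_patterns, compute_heterosis_stats,
                        intersect_upregulated, select_candidates)
from .io import (ExpressionMatrix, normalize_fpkm, read_edge_list,
                 read_expression, read_gene_lengths, read_gmt, write_table)
from .network import enrich, hub_genes
from .simulate import SimConfig, TraitSimSpec, simulate_expression, simulate_traits
from .traits import correlate_genes_traits, summarize_traits

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; exactly one of simulation / file inputs."""

    outdir: str
    seed: int = 0
    sim: SimConfig | None = None
    trait_sim: TraitSimSpec | None = None
    matrix: str | None = None
    sample_sheet: str | None = None
    gene_lengths: str | None = None
    traits: str | None = None
    edges: str | None = None
    gene_sets: str | None = None
    deg: DEGThresholds = field(default_factory=DEGThresholds)
    pattern: PatternCallConfig = field(default_factory=PatternCallConfig)
    min_mean_abundance: float = 1.0
    library_size: str = "median_ratio"
    moderation: bool = True
    top_k_hubs: int = 10
    pseudocount: float = 1.0
    force: bool = False

    def __post_init__(self) -> None:
        has_sim = self.sim is not None
        has_files = self.matrix is not None
        if has_sim == has_files:
            raise ConfigError("exactly one of a simulation block or input paths is required")
        if has_files and self.sample_sheet is None:
            raise ConfigError("a sample sheet is required with an input matrix")
        if self.trait_sim is not None and not has_sim:
            raise ConfigError("trait simulation requires a simulation block")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "sim" in raw and raw["sim"] is not None:
            sim = dict(raw["sim"])
            if "libsize_range" in sim:
                sim["libsize_range"] = tuple(sim["libsize_range"])
            if "baseline_range" in sim:
                sim["baseline_range"] = tuple(sim["baseline_range"])
            raw["sim"] = SimConfig(**sim)
        if "trait_sim" in raw and raw["trait_sim"] is not None:
            ts = dict(raw["trait_sim"])
            ts["driver_genes"] = {
                trait: [(g, float(w)) for g, w in drivers]
                for trait, drivers in ts["driver_genes"].items()
            }
            raw["trait_sim"] = TraitSimSpec(**ts)
        if "deg" in raw and raw["deg"] is not None:
            raw["deg"] = DEGThresholds(**raw["deg"])
        if "pattern" in raw and raw["pattern"] is not None:
            pat = dict(raw["pattern"])
            if "thresholds" in pat and pat["thresholds"] is not None:
                pat["thresholds"] = DEGThresholds(**pat["thresholds"])
            raw["pattern"] = PatternCallConfig(**pat)
        return cls(**raw)

    def to_dict(self) -> dict:
        out = asdict(self)
        # execution-only flag; excluded so reruns of one analysis are identical
        out.pop("force")
        if self.trait_sim is not None:
            out["trait_sim"]["driver_genes"] = {
                trait: [[g, w] for g, w in drivers]
                for trait, drivers in self.trait_sim.driver_genes.items()
            }
        if self.sim is not None:
            out["sim"]["libsize_range"] = list(self.sim.libsize_range)
            out["sim"]["baseline_range"] = list(self.sim.baseline_range)
        return out


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    try:
        yield
    except HetexError as exc:
        raise type(exc)(f"[{name}] {exc}") from exc
    except (LookupError, OSError, ValueError) as exc:
        raise HetexError(f"[{name}] {exc}") from exc
    logger.info("stage %-12s %.2fs", name, time.perf_counter() - t0)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run summary (also written as JSON)."""
    outdir = Path(config.outdir)
    if outdir.exists() and any(outdir.iterdir()) and not config.force:
        raise ConfigError(f"output directory {outdir} is not empty (use force=True)")
    outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    trait_table = None
    with _stage("input"):
        if config.sim is not None:
            sim = replace(config.sim, seed=config.seed)
            counts, truth = simulate_expression(sim)
            truth.to_csv(outdir / "truth.tsv", sep="\t", float_format="%.6g")
            if config.trait_sim is not None:
                trait_table = simulate_traits(counts, config.trait_sim, seed=config.seed + 1)
        else:
            counts = read_expression(config.matrix, config.sample_sheet)
            if config.traits is not None:
                trait_table = pd.read_csv(config.traits, sep="\t", index_col=0, comment="#")
        counts.write(outdir / "counts.tsv", outdir / "samples.tsv")
        if trait_table is not None:
            trait_table.to_csv(outdir / "traits.tsv", sep="\t", float_format="%.6g")

    with _stage("normalize"):
        lengths = read_gene_lengths(config.gene_lengths) if config.gene_lengths else None
        abundance = normalize_fpkm(counts, lengths, library_size=config.library_size)
        expressed = filter_expressed(abundance, config.min_mean_abundance)

    with _stage("deg"):
        deg_a = run_contrast(expressed, "parentA", "hybrid", config.deg,
                             config.pseudocount, config.moderation)
        deg_b = run_contrast(expressed, "parentB", "hybrid", config.deg,
                             config.pseudocount, config.moderation)
        write_table(deg_a, outdir / "deg_hybrid_vs_parentA.tsv", index=True)
        write_table(deg_b, outdir / "deg_hybrid_vs_parentB.tsv", index=True)

    with _stage("heterosis"):
        stats = compute_heterosis_stats(expressed, config.pattern.min_mpv)
        cls_a = apply_calls(deg_a, config.pattern.thresholds)
        cls_b = apply_calls(deg_b, config.pattern.thresholds)
        classified = classify_patterns(stats, cls_a, cls_b, config.pattern)
        write_table(classified, outdir / "heterosis.tsv", index=True)
        candidates = select_candidates(classified)
        cand_table = classified.loc[candidates, ["bph_pct", "mph_pct"]]
        write_table(cand_table, outdir / "candidates.tsv", index=True)
        # cross-check: the intersection of up-regulated sets is the
        # transgressive_up set (over genes with defined MPH)
        up_set = set(classified.index[classified["pattern"] == TRANSGRESSIVE_UP])
        inter = set(intersect_upregulated(cls_a, cls_b))
        defined = set(classified.index[classified["mph_pct"].notna()])
        if up_set != inter & defined:
            raise HetexError("internal inconsistency: transgressive_up != intersected up-sets")

    transgressive = classified.index[
        classified["pattern"].isin([TRANSGRESSIVE_UP, TRANSGRESSIVE_DOWN])
    ].tolist()

    hubs = None
    if config.edges is not None:
        with _stage("network"):
            edge_list = read_edge_list(config.edges)
            hubs = hub_genes(edge_list, transgressive, k=config.top_k_hubs)
            write_table(hubs, outdir / "hubs.tsv")

    enrichment = None
    if config.gene_sets is not None:
        with _stage("enrich"):
            sets = read_gmt(config.gene_sets)
            enrichment = enrich(sorted(up_set), sets, expressed.gene_ids)
            write_table(enrichment, outdir / "enrichment.tsv")

    corr = None
    if trait_table is not None:
        with _stage("traits"):
            summary_tbl = summarize_traits(trait_table)
            write_table(summary_tbl, outdir / "trait_summary.tsv")
            if hubs is not None and len(hubs):
                corr_genes = hubs["gene_id"].tolist()
            else:
                corr_genes = candidates[: config.top_k_hubs]
            corr_genes = [g for g in corr_genes if g in expressed.values.index]
            if corr_genes:
                corr = correlate_genes_traits(expressed, trait_table, corr_genes,
                                              pseudocount=config.pseudocount)
                write_table(corr, outdir / "correlations.tsv")

    with _stage("summary"):
        pattern_counts = classified["pattern"].value_counts().to_dict()
        summary = {
            "seed": config.seed,
            "versions": {
                "hetex": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
            },
            "counts": {
                "genes_input": int(len(counts.gene_ids)),
                "genes_expressed": int(len(expressed.gene_ids)),
                "deg_vs_parentA_up": int((deg_a["call"] == UP).sum()),
                "deg_vs_parentA_down": int((deg_a["call"] == DOWN).sum()),
                "deg_vs_parentB_up": int((deg_b["call"] == UP).sum()),
                "deg_vs_parentB_down": int((deg_b["call"] == DOWN).sum()),
                "transgressive_up": int(pattern_counts.get(TRANSGRESSIVE_UP, 0)),
                "transgressive_down": int(pattern_counts.get(TRANSGRESSIVE_DOWN, 0)),
                "additive_like": int(pattern_counts.get("additive_like", 0)),
                "dominant_like": int(pattern_counts.get("dominant_like", 0)),
                "unclassified": int(pattern_counts.get("unclassified", 0)),
                "undefined_mpv": int(classified["mph_pct"].isna().sum()),
                "candidates": int(len(candidates)),
                "hub_genes": int(len(hubs)) if hubs is not None else None,
                "enriched_sets_bh05": (
                    int((enrichment["p_adjusted"] < 0.05).sum())
                    if enrichment is not None and len(enrichment) else
                    (0 if enrichment is not None else None)
                ),
            },
            "config": config.to_dict(),
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(outdir / "config_resolved.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return summary
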