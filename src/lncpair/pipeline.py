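"""End-to-end orchestration: load -> filter -> DE -> annotate -> pairs -> report.

One configuration object drives a full run.  All thresholds default to the
conventional values for this kind of analysis: presence cutoff mean FPKM 1,
significance raw p < 0.05, annotation windows 5 kb upstream / 1 kb
downstream.  Every output table is a pandas DataFrame; ``write_bundle``
serializes them as TSV so a run is reproducible and auditable from the
config and seed alone.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import expression as xp
from .expression import Comparison, DEResult, ExpressionPartition, format_fold_change
from .gene_models import read_gene_gtf, read_lncrna_gtf, build_index
from .genomic_annotation import (
    AnnotationRecord,
    Category,
    annotate_all,
    annotation_frame,
    category_distribution,
)
from .pairing import PairRecord, identify_pairs, pair_counting_chain, pairs_frame
from .setops import pattern_table, venn_counts_frame, venn_partition
from .simulate import default_comparisons

__all__ = [
    "PipelineConfig",
    "ReportBundle",
    "run_pipeline",
    "top_regulated",
    "write_bundle",
]

log = logging.getLogger("lncpair")


@dataclass
class PipelineConfig:
    """Paths, contrasts, and thresholds for one pipeline run."""

    gene_gtf: str
    lncrna_gtf: str
    gene_expression: str
    lnc_expression: str
    groups: str
    comparisons: tuple[Comparison, ...] = field(default_factory=default_comparisons)
    gene_de_table: Optional[str] = None  # imported instead of the built-in test
    lnc_de_table: Optional[str] = None
    alpha: float = 0.05
    adjust: str = "none"
    min_fpkm: float = 1.0
    upstream_window: int = 5000
    downstream_window: int = 1000
    top_k: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        comparisons = raw.pop("comparisons", None)
        cfg = cls(**raw)
        if comparisons is not None:
            cfg.comparisons = tuple(
                Comparison(c["name"], c["control"], c["treated"])
                for c in comparisons
            )
        return cfg


@dataclass
class ReportBundle:
    """All tables a run produces, keyed the way the reports name them."""

    gene_partition: ExpressionPartition
    lnc_partition: ExpressionPartition
    gene_de: dict[str, list[DEResult]]
    lnc_de: dict[str, list[DEResult]]
    annotations: list[AnnotationRecord]
    category_distributions: dict[str, pd.DataFrame]
    gene_venn: dict
    lnc_venn: dict
    gene_patterns: pd.DataFrame
    lnc_patterns: pd.DataFrame
    pairs: dict[str, list[PairRecord]]
    counting_chain: pd.DataFrame
    top_tables: dict[str, tuple[pd.DataFrame, pd.DataFrame]]


def _de_stage(matrix: xp.ExpressionMatrix, comparisons: Sequence[Comparison],
              alpha: float, adjust: str, min_fpkm: float,
              imported: Optional[str]) -> dict[str, list[DEResult]]:
    if imported is not None:
        results = xp.import_de_table(imported, alpha=alpha)
        by_comparison: dict[str, list[DEResult]] = {c.name: [] for c in comparisons}
        for r in results:
            if r.comparison in by_comparison:
                by_comparison[r.comparison].append(r)
        return by_comparison
    expressed = xp.expressed_features(matrix, threshold=min_fpkm)
    sub = matrix.subset(expressed)
    return {
        c.name: xp.run_de(sub, c, alpha=alpha, adjust=adjust)
        for c in comparisons
    }


def _significant_ids(results: Sequence[DEResult]) -> set[str]:
    return {r.feature_id for r in results if r.significant}


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis chain and return every report table."""
    log.info("loading annotations: %s, %s", config.gene_gtf, config.lncrna_gtf)
    genes = read_gene_gtf(config.gene_gtf)
    lncs = read_lncrna_gtf(config.lncrna_gtf)
    log.info("loaded %d genes, %d lncRNA loci", len(genes), len(lncs))

    gene_matrix = xp.read_expression_tsv(config.gene_expression, config.groups)
    lnc_matrix = xp.read_expression_tsv(config.lnc_expression, config.groups)
    log.info("expression: %d gene features, %d lncRNA features, %d samples",
             len(gene_matrix.feature_ids), len(lnc_matrix.feature_ids),
             len(gene_matrix.sample_ids))

    gene_de = _de_stage(gene_matrix, config.comparisons, config.alpha,
                        config.adjust, config.min_fpkm, config.gene_de_table)
    lnc_de = _de_stage(lnc_matrix, config.comparisons, config.alpha,
                       config.adjust, config.min_fpkm, config.lnc_de_table)

    all_gene_de = [r for rs in gene_de.values() for r in rs]
    all_lnc_de = [r for rs in lnc_de.values() for r in rs]
    gene_partition = xp.partition_features(gene_matrix, all_gene_de,
                                           threshold=config.min_fpkm)
    lnc_partition = xp.partition_features(lnc_matrix, all_lnc_de,
                                          threshold=config.min_fpkm)
    log.info("gene partition: %s", gene_partition.sizes())
    log.info("lncRNA partition: %s", lnc_partition.sizes())

    index = build_index(genes)
    annotations = annotate_all(lncs.values(), index,
                               upstream_window=config.upstream_window,
                               downstream_window=config.downstream_window)
    annotated_ids = {a.lnc_id for a in annotations}

    category_distributions = {}
    for name, results in lnc_de.items():
        subset = sorted(_significant_ids(results) & annotated_ids)
        category_distributions[name] = category_distribution(
            annotations, subset).as_frame()

    gene_sets = {name: _significant_ids(rs) for name, rs in gene_de.items()}
    lnc_sets = {name: _significant_ids(rs) for name, rs in lnc_de.items()}
    gene_venn = venn_partition(gene_sets)
    lnc_venn = venn_partition(lnc_sets)

    order = tuple(c.name for c in config.comparisons)
    gene_patterns = pattern_table(all_gene_de, comparisons=order)
    lnc_patterns = pattern_table(all_lnc_de, comparisons=order)

    pairs = {
        name: identify_pairs(annotations, lnc_de[name], gene_de[name], name)
        for name in order
    }
    for name in order:
        log.info("%s: %d pairs", name, len(pairs[name]))
    chain = pair_counting_chain(lnc_de, annotations, pairs)

    top_tables = {name: top_regulated(gene_de[name], config.top_k)
                  for name in order}

    return ReportBundle(
        gene_partition=gene_partition,
        lnc_partition=lnc_partition,
        gene_de=gene_de,
        lnc_de=lnc_de,
        annotations=annotations,
        category_distributions=category_distributions,
        gene_venn=gene_venn,
        lnc_venn=lnc_venn,
        gene_patterns=gene_patterns,
        lnc_patterns=lnc_patterns,
        pairs=pairs,
        counting_chain=chain,
        top_tables=top_tables,
    )


def top_regulated(de_results: Sequence[DEResult], k: int,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k significant features by fold-increase and by percent decrease.

    Returns (up_table, down_table); each is shorter than k when fewer
    significant features exist.  Ties break on feature id.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ups, downs = [], []
    for r in de_results:
        if not r.significant:
            continue
        fc = format_fold_change(r.control_mean, r.treated_mean)
        if fc.kind == "fold_increase":
            ups.append((r.feature_id, fc.value, r.p_value))
        else:
            downs.append((r.feature_id, fc.value, r.p_value))
    ups.sort(key=lambda t: (-t[1], t[0]))
    downs.sort(key=lambda t: (-t[1], t[0]))
    up_frame = pd.DataFrame(ups[:k], columns=["feature_id", "fold_increase",
                                              "p_value"])
    down_frame = pd.DataFrame(downs[:k], columns=["feature_id", "percent_decrease",
                                                  "p_value"])
    return up_frame, down_frame


def _partition_frame(name: str, partition: ExpressionPartition) -> pd.DataFrame:
    sizes = partition.sizes()
    return pd.DataFrame({
        "feature_class": [name] * 3,
        "stratum": list(sizes),
        "count": [sizes[s] for s in sizes],
    })


def write_bundle(bundle: ReportBundle, directory: str) -> None:
    """Serialize every report table as TSV under ``directory``."""
    os.makedirs(directory, exist_ok=True)

    def path(name: str) -> str:
        return os.path.join(directory, name)

    pd.concat([
        _partition_frame("PCG", bundle.gene_partition),
        _partition_frame("lncRNA", bundle.lnc_partition),
    ]).to_csv(path("expression_partition.tsv"), sep="\t", index=False)

    xp.de_to_frame(
        [r for rs in bundle.gene_de.values() for r in rs]
    ).to_csv(path("gene_de.tsv"), sep="\t", index=False)
    xp.de_to_frame(
        [r for rs in bundle.lnc_de.values() for r in rs]
    ).to_csv(path("lnc_de.tsv"), sep="\t", index=False)

    annotation_frame(bundle.annotations).to_csv(
        path("lnc_annotation.tsv"), sep="\t", index=False)

    for name, frame in bundle.category_distributions.items():
        frame.to_csv(path(f"category_distribution_{name}.tsv"),
                     sep="\t", index=False)

    venn_counts_frame(bundle.gene_venn).to_csv(
        path("gene_venn.tsv"), sep="\t", index=False)
    venn_counts_frame(bundle.lnc_venn).to_csv(
        path("lnc_venn.tsv"), sep="\t", index=False)

    bundle.gene_patterns.to_csv(path("gene_patterns.tsv"), sep="\t", index=False)
    bundle.lnc_patterns.to_csv(path("lnc_patterns.tsv"), sep="\t", index=False)

    pairs_frame(
        [p for ps in bundle.pairs.values() for p in ps]
    ).to_csv(path("pairs.tsv"), sep="\t", index=False)

    bundle.counting_chain.to_csv(path("counting_chain.tsv"), sep="\t",
                                 index_label="stage")

    for name, (up, down) in bundle.top_tables.items():
        up.to_csv(path(f"top_up_{name}.tsv"), sep="\t", index=False)
        down.to_csv(path(f"top_down_{name}.tsv"), sep="\t", index=False)
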