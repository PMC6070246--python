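"""Synthetic genomes and expression matrices with known ground truth.

The generator emulates the statistical structure of a six-group mouse-liver
toxicogenomics design: two enterotypes (conventional / germ-free) x three
treatments (vehicle, BDE-47, BDE-99), with small unbalanced group sizes
(3, 4, 2, 3, 3, 3 by default).  Expression is log-normal FPKM with a large
non-expressed fraction; treatment effects are planted log2 fold-changes in
the treated group of a chosen comparison.  lncRNA loci are placed by quota
at known genomic categories against non-overlapping coding genes, and a
configurable number of co-regulated lncRNA-gene pairs (lncRNA intronic in
its host gene) is planted with a controlled direction-concordance mix.

Placements are verified internally by re-annotation: a configuration whose
planted categories cannot be realized raises before anything is emitted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .expression import Comparison, ExpressionMatrix, read_expression_tsv
from .gene_models import (
    GeneModel,
    GenomicInterval,
    LncRNALocus,
    read_gene_gtf,
    read_lncrna_gtf,
    write_gene_gtf,
    write_lncrna_gtf,
)
from .genomic_annotation import (
    Category,
    annotate_all,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PlantedPair",
    "SimulatedBundle",
    "SimulationError",
    "DEFAULT_GROUPS",
    "DEFAULT_GROUP_SIZES",
    "default_comparisons",
    "generate_genome",
    "generate_expression",
    "simulate_bundle",
    "write_fixture",
    "read_fixture",
]

DEFAULT_GROUPS = ("CV_CO", "CV_BDE-47", "CV_BDE-99", "GF_CO", "GF_BDE-47", "GF_BDE-99")
DEFAULT_GROUP_SIZES = (3, 4, 2, 3, 3, 3)

DEFAULT_CATEGORY_PROPORTIONS = {
    Category.INTRON: 0.44,
    Category.INTERGENIC: 0.26,
    Category.UTR3: 0.16,
    Category.DOWNSTREAM: 0.05,
    Category.UPSTREAM: 0.04,
    Category.EXON: 0.04,
    Category.UTR5: 0.01,
}


class SimulationError(ValueError):
    """The configuration cannot be realized as a concrete genome/matrix."""


def default_comparisons() -> tuple[Comparison, ...]:
    """The four treated-vs-vehicle contrasts, one per congener per enterotype."""
    return (
        Comparison("CV_CO_vs_CV_BDE-47", "CV_CO", "CV_BDE-47"),
        Comparison("CV_CO_vs_CV_BDE-99", "CV_CO", "CV_BDE-99"),
        Comparison("GF_CO_vs_GF_BDE-47", "GF_CO", "GF_BDE-47"),
        Comparison("GF_CO_vs_GF_BDE-99", "GF_CO", "GF_BDE-99"),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """All tunables of the generator; defaults mirror the emulated study design."""

    n_genes: int = 80
    n_lncrnas: int = 300
    n_chromosomes: int = 4
    # gene structure (bp)
    exon_count_range: tuple[int, int] = (3, 6)
    exon_length_range: tuple[int, int] = (150, 400)
    intron_length_range: tuple[int, int] = (500, 3000)
    utr_min_length: int = 60
    intergene_gap_range: tuple[int, int] = (20000, 40000)
    lnc_length_range: tuple[int, int] = (200, 2000)
    chromosome_length: Optional[int] = None  # None: sized to fit the layout
    category_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROPORTIONS)
    )
    # expression
    group_labels: tuple[str, ...] = DEFAULT_GROUPS
    group_sizes: tuple[int, ...] = DEFAULT_GROUP_SIZES
    fraction_nonexpressed: float = 0.55
    baseline_log2_mean: float = 3.5
    baseline_log2_sd: float = 1.5
    baseline_log2_min: float = 1.0
    de_fraction: float = 0.05
    effect_size: float = 2.0
    effect_size_sd: float = 0.25
    noise_sd: float = 0.25
    n_pairs: int = 20
    pair_same_direction_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_lncrnas < 1 or self.n_chromosomes < 1:
            raise SimulationError("counts must be positive (and n_genes >= 2)")
        if len(self.group_labels) != len(self.group_sizes):
            raise SimulationError("group_labels and group_sizes lengths differ")
        if any(n < 1 for n in self.group_sizes):
            raise SimulationError("every group needs at least one sample")
        total = sum(self.category_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(
                f"category proportions must sum to 1, got {total}"
            )
        if not 0.0 <= self.fraction_nonexpressed < 1.0:
            raise SimulationError("fraction_nonexpressed must be in [0, 1)")
        if self.exon_count_range[0] < 2:
            raise SimulationError(
                "genes need >= 2 exons so that introns and both UTRs exist"
            )
        if self.exon_length_range[0] < 2 * self.utr_min_length + 1:
            raise SimulationError(
                "min exon length must exceed twice utr_min_length"
            )
        if self.intergene_gap_range[0] < 2 * 5001 + self.lnc_length_range[1]:
            raise SimulationError(
                "intergenic gaps too small to host intergenic lncRNAs outside "
                "all annotation windows"
            )

    @property
    def comparisons(self) -> tuple[Comparison, ...]:
        return default_comparisons()

    def sample_ids(self) -> list[str]:
        out = []
        for label, n in zip(self.group_labels, self.group_sizes):
            out.extend(f"{label}_{i + 1}" for i in range(n))
        return out

    def groups_map(self) -> dict[str, str]:
        out = {}
        for label, n in zip(self.group_labels, self.group_sizes):
            for i in range(n):
                out[f"{label}_{i + 1}"] = label
        return out


@dataclass(frozen=True)
class PlantedPair:
    lnc_id: str
    gene_id: str
    comparison: str
    concordance: str  # "same" or "opposite"
    lnc_log2fc: float = 0.0
    gene_log2fc: float = 0.0


@dataclass
class GroundTruth:
    """Planted facts the pipeline is expected to recover."""

    lnc_category: dict[str, Category]
    lnc_closest_gene: dict[str, Optional[str]]
    planted_pairs: list[PlantedPair]
    # filled by generate_expression:
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    baselines: dict[str, float] = field(default_factory=dict)
    expressed: dict[str, bool] = field(default_factory=dict)

    def de_features(self, comparison: Comparison) -> set[str]:
        treated = comparison.treated_group
        return {f for f, eff in self.effects.items() if eff.get(treated)}


@dataclass
class SimulatedBundle:
    config: SimulationConfig
    genes: dict[str, GeneModel]
    lncs: dict[str, LncRNALocus]
    truth: GroundTruth
    gene_expression: ExpressionMatrix
    lnc_expression: ExpressionMatrix


# --------------------------------------------------------------------------
# genome layout
# --------------------------------------------------------------------------

def _quota_counts(proportions: dict, total: int) -> dict:
    """Exact per-category counts by largest remainder (Hamilton apportionment)."""
    raw = {c: p * total for c, p in proportions.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    remainder = total - sum(counts.values())
    order = sorted(raw, key=lambda c: (-(raw[c] - counts[c]), str(c)))
    for c in order[:remainder]:
        counts[c] += 1
    return counts


def _build_gene(rng: np.random.Generator, cfg: SimulationConfig,
                gene_id: str, chrom: str, start: int) -> GeneModel:
    n_exons = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
    exons = []
    cursor = start
    for i in range(n_exons):
        length = int(rng.integers(*cfg.exon_length_range))
        exons.append(GenomicInterval(chrom, cursor, cursor + length, "."))
        cursor += length
        if i < n_exons - 1:
            cursor += int(rng.integers(*cfg.intron_length_range))
    strand = "+" if rng.random() < 0.5 else "-"
    span = GenomicInterval(chrom, start, exons[-1].end, strand)
    exons = tuple(GenomicInterval(chrom, e.start, e.end, strand) for e in exons)
    first, last = exons[0], exons[-1]
    utr_a = int(rng.integers(cfg.utr_min_length, len(first) - cfg.utr_min_length))
    utr_b = int(rng.integers(cfg.utr_min_length, len(last) - cfg.utr_min_length))
    return GeneModel(gene_id=gene_id, span=span, exons=exons,
                     cds_start=first.start + utr_a, cds_end=last.end - utr_b)


def _pick_base(rng: np.random.Generator, intervals: list[tuple[int, int]]) -> int:
    """Uniform random base over a union of half-open integer intervals."""
    intervals = [(s, e) for s, e in intervals if e > s]
    if not intervals:
        raise SimulationError("no bases available for the requested placement")
    sizes = np.array([e - s for s, e in intervals], dtype=float)
    i = int(rng.choice(len(intervals), p=sizes / sizes.sum()))
    s, e = intervals[i]
    return int(rng.integers(s, e))


def _anchor_for_category(rng: np.random.Generator, cfg: SimulationConfig,
                         category: Category, gene: GeneModel) -> int:
    span, exons = gene.span, gene.exons
    if category is Category.INTRON:
        introns = [(iv.start, iv.end) for iv in gene.introns()]
        return _pick_base(rng, introns)
    if category is Category.EXON:
        cds = [(max(e.start, gene.cds_start), min(e.end, gene.cds_end))
               for e in exons]
        return _pick_base(rng, cds)
    if category is Category.UTR5:
        if gene.strand == "+":
            region = [(e.start, min(e.end, gene.cds_start)) for e in exons]
        else:
            region = [(max(e.start, gene.cds_end), e.end) for e in exons]
        return _pick_base(rng, region)
    if category is Category.UTR3:
        if gene.strand == "+":
            region = [(max(e.start, gene.cds_end), e.end) for e in exons]
        else:
            region = [(e.start, min(e.end, gene.cds_start)) for e in exons]
        return _pick_base(rng, region)
    if category is Category.UPSTREAM:
        d = int(rng.integers(1, 5001))
        return span.start - d if gene.strand == "+" else span.end - 1 + d
    if category is Category.DOWNSTREAM:
        d = int(rng.integers(1, 1001))
        return span.end - 1 + d if gene.strand == "+" else span.start - d
    raise SimulationError(f"no anchored placement for category {category}")


def _lnc_span(rng: np.random.Generator, cfg: SimulationConfig,
              chrom: str, anchor: int) -> GenomicInterval:
    """A lncRNA span whose strand-aware 5' end sits exactly at ``anchor``."""
    length = int(rng.integers(*cfg.lnc_length_range))
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-" and anchor - length + 1 < 0:
        strand = "+"
    if strand == "+":
        return GenomicInterval(chrom, anchor, anchor + length, "+")
    return GenomicInterval(chrom, anchor - length + 1, anchor + 1, "-")


def generate_genome(config: SimulationConfig,
                    ) -> tuple[dict[str, GeneModel], dict[str, LncRNALocus], GroundTruth]:
    """Lay out non-overlapping genes and quota-placed lncRNA loci.

    Every lncRNA's planted category is verified by re-annotation before the
    genome is returned; the planted pairs are intronic lncRNAs with distinct
    host genes, so pairing criterion 1 holds by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    genes: dict[str, GeneModel] = {}
    per_chrom: dict[str, list[GeneModel]] = {c: [] for c in chroms}
    cursors = {c: int(rng.integers(*config.intergene_gap_range)) for c in chroms}
    for i in range(config.n_genes):
        chrom = chroms[i % len(chroms)]
        gid = f"GENE{i + 1:04d}"
        gene = _build_gene(rng, config, gid, chrom, cursors[chrom])
        gap = int(rng.integers(*config.intergene_gap_range))
        cursors[chrom] = gene.span.end + gap
        genes[gid] = gene
        per_chrom[chrom].append(gene)

    if config.chromosome_length is not None:
        for chrom, cursor in cursors.items():
            if cursor > config.chromosome_length:
                raise SimulationError(
                    f"{chrom}: layout needs {cursor} bp but chromosome_length "
                    f"is {config.chromosome_length}"
                )

    # intergenic safe zones: internal gaps, margins past both windows
    margin = 5001
    zones = []
    for chrom in chroms:
        gs = per_chrom[chrom]
        for left, right in zip(gs, gs[1:]):
            lo = left.span.end + margin
            hi = right.span.start - margin
            if hi - lo > config.lnc_length_range[1]:
                zones.append((chrom, lo, hi))
    counts = _quota_counts(config.category_proportions, config.n_lncrnas)
    if counts.get(Category.INTERGENIC, 0) and not zones:
        raise SimulationError(
            "no intergenic zone wide enough; enlarge intergene_gap_range "
            "or add genes per chromosome"
        )

    gene_list = list(genes.values())
    lncs: dict[str, LncRNALocus] = {}
    lnc_category: dict[str, Category] = {}
    lnc_closest: dict[str, Optional[str]] = {}

    assignments: list[Category] = []
    for category in sorted(counts, key=str):
        assignments.extend([category] * counts[category])
    rng.shuffle(assignments)  # interleave categories across ids

    # reserve intronic placements with distinct host genes for planted pairs
    if config.n_pairs > counts.get(Category.INTRON, 0):
        raise SimulationError(
            f"n_pairs={config.n_pairs} exceeds the intronic quota "
            f"({counts.get(Category.INTRON, 0)})"
        )
    pair_hosts = list(rng.choice(len(gene_list), size=config.n_pairs,
                                 replace=False))
    pair_skeletons: list[tuple[str, str]] = []
    intron_seen = 0

    for i, category in enumerate(assignments):
        lnc_id = f"LNC{i + 1:05d}"
        if category is Category.INTERGENIC:
            chrom, lo, hi = zones[int(rng.integers(len(zones)))]
            length = int(rng.integers(*config.lnc_length_range))
            start = int(rng.integers(lo, hi - length))
            strand = "+" if rng.random() < 0.5 else "-"
            span = GenomicInterval(chrom, start, start + length, strand)
            lncs[lnc_id] = LncRNALocus(lnc_id, span)
            lnc_closest[lnc_id] = None
        else:
            if category is Category.INTRON and intron_seen < config.n_pairs:
                gene = gene_list[pair_hosts[intron_seen]]
                pair_skeletons.append((lnc_id, gene.gene_id))
                intron_seen += 1
            else:
                gene = gene_list[int(rng.integers(len(gene_list)))]
            anchor = _anchor_for_category(rng, config, category, gene)
            span = _lnc_span(rng, config, gene.chrom, anchor)
            lncs[lnc_id] = LncRNALocus(lnc_id, span)
            lnc_closest[lnc_id] = gene.gene_id
        lnc_category[lnc_id] = category

    # closure check: re-annotation must reproduce every planted category
    records = annotate_all(lncs.values(), genes)
    for record in records:
        planted = lnc_category[record.lnc_id]
        if record.category is not planted:
            raise SimulationError(
                f"{record.lnc_id}: planted {planted} but re-annotated as "
                f"{record.category} (closest gene {record.closest_gene_id})"
            )
        if (planted is not Category.INTERGENIC
                and record.closest_gene_id != lnc_closest[record.lnc_id]):
            raise SimulationError(
                f"{record.lnc_id}: intended host {lnc_closest[record.lnc_id]} "
                f"but closest gene is {record.closest_gene_id}"
            )

    comparisons = config.comparisons
    n_same = int(round(config.pair_same_direction_fraction * len(pair_skeletons)))
    planted_pairs = []
    for j, (lnc_id, gene_id) in enumerate(pair_skeletons):
        planted_pairs.append(PlantedPair(
            lnc_id=lnc_id,
            gene_id=gene_id,
            comparison=comparisons[j % len(comparisons)].name,
            concordance="same" if j < n_same else "opposite",
        ))

    truth = GroundTruth(
        lnc_category=lnc_category,
        lnc_closest_gene=lnc_closest,
        planted_pairs=planted_pairs,
    )
    return genes, lncs, truth


# --------------------------------------------------------------------------
# expression
# --------------------------------------------------------------------------

def _draw_magnitude(rng: np.random.Generator, cfg: SimulationConfig) -> float:
    return float(max(0.5, rng.normal(cfg.effect_size, cfg.effect_size_sd)))


def generate_expression(config: SimulationConfig,
                        genes: dict[str, GeneModel],
                        lncs: dict[str, LncRNALocus],
                        truth: GroundTruth,
                        ) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Simulate FPKM matrices for genes and lncRNAs with planted effects.

    FPKM(feature, sample) = baseline * 2**effect(group) * 2**N(0, noise_sd).
    Planted pair members are forced into the expressed stratum; background
    differentially expressed features are chosen so they cannot form
    accidental pairs with each other or with the planted pairs (the planted
    pair list is the complete ground-truth pair set).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    comparisons = config.comparisons
    treated_of = {c.name: c.treated_group for c in comparisons}

    pair_lncs = {p.lnc_id for p in truth.planted_pairs}
    pair_genes = {p.gene_id for p in truth.planted_pairs}

    gene_ids = sorted(genes)
    lnc_ids = sorted(lncs)
    all_ids = gene_ids + lnc_ids

    expressed: dict[str, bool] = {}
    baselines: dict[str, float] = {}
    for fid in all_ids:
        forced = fid in pair_lncs or fid in pair_genes
        is_expr = forced or rng.random() >= config.fraction_nonexpressed
        expressed[fid] = bool(is_expr)
        if is_expr:
            log2_base = max(config.baseline_log2_min,
                            rng.normal(config.baseline_log2_mean,
                                       config.baseline_log2_sd))
            baselines[fid] = float(2.0 ** log2_base)
        else:
            baselines[fid] = float(rng.uniform(0.001, 0.1))

    effects: dict[str, dict[str, float]] = {}

    def set_effect(fid: str, group: str, log2fc: float) -> None:
        effects.setdefault(fid, {})[group] = log2fc

    planted_pairs = []
    for pair in truth.planted_pairs:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        lnc_fc = sign * _draw_magnitude(rng, config)
        gene_sign = sign if pair.concordance == "same" else -sign
        gene_fc = gene_sign * _draw_magnitude(rng, config)
        group = treated_of[pair.comparison]
        set_effect(pair.lnc_id, group, lnc_fc)
        set_effect(pair.gene_id, group, gene_fc)
        planted_pairs.append(replace(pair, lnc_log2fc=lnc_fc, gene_log2fc=gene_fc))

    # background DE lncRNAs: expressed, unpaired, and not adjacent to any
    # pair gene so they cannot pair accidentally
    lnc_candidates = [
        l for l in lnc_ids
        if expressed[l] and l not in pair_lncs
        and (truth.lnc_closest_gene.get(l) is None
             or truth.lnc_closest_gene[l] not in pair_genes)
    ]
    de_lnc_hosts: set[str] = set()
    n_extra = int(np.floor(config.de_fraction * len(lnc_candidates)))
    for comparison in comparisons:
        if not lnc_candidates or n_extra == 0:
            break
        chosen = rng.choice(len(lnc_candidates), size=min(n_extra, len(lnc_candidates)),
                            replace=False)
        for idx in chosen:
            lnc_id = lnc_candidates[int(idx)]
            sign = 1.0 if rng.random() < 0.5 else -1.0
            set_effect(lnc_id, treated_of[comparison.name],
                       sign * _draw_magnitude(rng, config))
            host = truth.lnc_closest_gene.get(lnc_id)
            if host is not None:
                de_lnc_hosts.add(host)

    # background DE genes: expressed, unpaired, never the closest gene of a
    # DE lncRNA
    gene_candidates = [
        g for g in gene_ids
        if expressed[g] and g not in pair_genes and g not in de_lnc_hosts
    ]
    n_extra_genes = int(np.floor(config.de_fraction * len(gene_candidates)))
    for comparison in comparisons:
        if not gene_candidates or n_extra_genes == 0:
            break
        chosen = rng.choice(len(gene_candidates),
                            size=min(n_extra_genes, len(gene_candidates)),
                            replace=False)
        for idx in chosen:
            gid = gene_candidates[int(idx)]
            sign = 1.0 if rng.random() < 0.5 else -1.0
            set_effect(gid, treated_of[comparison.name],
                       sign * _draw_magnitude(rng, config))

    sample_ids = config.sample_ids()
    groups_map = config.groups_map()

    def build_matrix(ids: list[str]) -> ExpressionMatrix:
        base = np.array([baselines[f] for f in ids])[:, None]
        effect_matrix = np.zeros((len(ids), len(sample_ids)))
        for i, fid in enumerate(ids):
            eff = effects.get(fid)
            if not eff:
                continue
            for j, sample in enumerate(sample_ids):
                effect_matrix[i, j] = eff.get(groups_map[sample], 0.0)
        noise = rng.normal(0.0, config.noise_sd, size=effect_matrix.shape)
        values = base * np.power(2.0, effect_matrix + noise)
        frame = pd.DataFrame(values, index=ids, columns=sample_ids)
        return ExpressionMatrix(frame, dict(groups_map))

    gene_matrix = build_matrix(gene_ids)
    lnc_matrix = build_matrix(lnc_ids)

    truth.effects = effects
    truth.baselines = baselines
    truth.expressed = expressed
    truth.planted_pairs = planted_pairs
    return gene_matrix, lnc_matrix, truth


def simulate_bundle(config: SimulationConfig) -> SimulatedBundle:
    """Full synthetic dataset: genome, loci, matrices, and the ground truth."""
    genes, lncs, truth = generate_genome(config)
    gene_expr, lnc_expr, truth = generate_expression(config, genes, lncs, truth)
    return SimulatedBundle(config=config, genes=genes, lncs=lncs, truth=truth,
                           gene_expression=gene_expr, lnc_expression=lnc_expr)


# --------------------------------------------------------------------------
# fixture I/O
# --------------------------------------------------------------------------

FIXTURE_FILES = {
    "genes": "genes.gtf",
    "lncrnas": "lncrnas.gtf",
    "gene_fpkm": "gene_fpkm.tsv",
    "lnc_fpkm": "lnc_fpkm.tsv",
    "groups": "groups.tsv",
    "truth_loci": "truth_loci.tsv",
    "truth_effects": "truth_effects.tsv",
    "truth_pairs": "truth_pairs.tsv",
}


def write_fixture(bundle: SimulatedBundle, directory: str) -> dict[str, str]:
    """Write the bundle as plain-text files; returns the path map."""
    os.makedirs(directory, exist_ok=True)
    paths = {k: os.path.join(directory, v) for k, v in FIXTURE_FILES.items()}

    write_gene_gtf(bundle.genes.values(), paths["genes"])
    write_lncrna_gtf(bundle.lncs.values(), paths["lncrnas"])
    bundle.gene_expression.values.round(6).to_csv(
        paths["gene_fpkm"], sep="\t", index_label="feature_id")
    bundle.lnc_expression.values.round(6).to_csv(
        paths["lnc_fpkm"], sep="\t", index_label="feature_id")
    groups = bundle.gene_expression.groups
    pd.DataFrame(
        {"sample_id": list(groups), "group": [groups[s] for s in groups]}
    ).to_csv(paths["groups"], sep="\t", index=False)

    truth = bundle.truth
    pd.DataFrame({
        "lnc_id": sorted(truth.lnc_category),
        "category": [truth.lnc_category[l].value for l in sorted(truth.lnc_category)],
        "closest_gene": [truth.lnc_closest_gene.get(l) or ""
                         for l in sorted(truth.lnc_category)],
    }).to_csv(paths["truth_loci"], sep="\t", index=False)

    effect_rows = [
        (fid, group, fc)
        for fid in sorted(truth.effects)
        for group, fc in sorted(truth.effects[fid].items())
    ]
    pd.DataFrame(effect_rows, columns=["feature_id", "group", "log2fc"]).to_csv(
        paths["truth_effects"], sep="\t", index=False)

    pd.DataFrame(
        [(p.lnc_id, p.gene_id, p.comparison, p.concordance,
          round(p.lnc_log2fc, 6), round(p.gene_log2fc, 6))
         for p in truth.planted_pairs],
        columns=["lnc_id", "gene_id", "comparison", "concordance",
                 "lnc_log2fc", "gene_log2fc"],
    ).to_csv(paths["truth_pairs"], sep="\t", index=False)
    return paths


def read_fixture(directory: str) -> dict:
    """Re-read a written fixture into in-memory objects."""
    paths = {k: os.path.join(directory, v) for k, v in FIXTURE_FILES.items()}
    genes = read_gene_gtf(paths["genes"])
    lncs = read_lncrna_gtf(paths["lncrnas"])
    gene_expr = read_expression_tsv(paths["gene_fpkm"], paths["groups"])
    lnc_expr = read_expression_tsv(paths["lnc_fpkm"], paths["groups"])
    loci = pd.read_csv(paths["truth_loci"], sep="\t")
    effects = pd.read_csv(paths["truth_effects"], sep="\t")
    pairs = pd.read_csv(paths["truth_pairs"], sep="\t")
    return {
        "genes": genes,
        "lncs": lncs,
        "gene_expression": gene_expr,
        "lnc_expression": lnc_expr,
        "truth_loci": loci,
        "truth_effects": effects,
        "truth_pairs": pairs,
    }
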