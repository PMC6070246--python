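"""Gene models parsed from GTF and query-ready interval indexes.

Internal coordinates are 0-based half-open throughout; GTF I/O (1-based,
fully closed) converts at the boundary.  Multi-transcript genes collapse to
a single gene-level model: the exon set is the union of exon footprints
across transcripts, and the CDS bounds are the outermost CDS coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "LncRNALocus",
    "FeatureIndex",
    "GtfParseError",
    "GeneValidationError",
    "read_gene_gtf",
    "read_lncrna_gtf",
    "write_gene_gtf",
    "write_lncrna_gtf",
    "build_index",
    "merge_intervals",
]

STRANDS = ("+", "-", ".")


class GtfParseError(ValueError):
    """A GTF line could not be parsed; the message names the line number."""


class GeneValidationError(ValueError):
    """A gene's records are internally inconsistent; the message names the gene."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: sorted, with overlapping/adjacent-identical runs merged."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged


@dataclass(frozen=True)
class GeneModel:
    """One protein-coding gene: span, strand, exon union, optional CDS bounds.

    The transcription start site (TSS) is the strand-aware 5' end of the span:
    ``span.start`` on + and ``span.end - 1`` on -.  The transcription
    termination site (TTS) is the opposite end.
    """

    gene_id: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.span.strand not in ("+", "-"):
            raise GeneValidationError(
                f"gene {self.gene_id}: span strand must be + or -, got {self.span.strand!r}"
            )
        prev_end = -1
        for exon in self.exons:
            if exon.chrom != self.span.chrom:
                raise GeneValidationError(
                    f"gene {self.gene_id}: exon on {exon.chrom} but span on {self.span.chrom}"
                )
            if exon.start < self.span.start or exon.end > self.span.end:
                raise GeneValidationError(
                    f"gene {self.gene_id}: exon [{exon.start},{exon.end}) outside "
                    f"span [{self.span.start},{self.span.end})"
                )
            if exon.start < prev_end:
                raise GeneValidationError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
            prev_end = exon.end
        if (self.cds_start is None) != (self.cds_end is None):
            raise GeneValidationError(
                f"gene {self.gene_id}: cds_start and cds_end must both be set or absent"
            )
        if self.cds_start is not None:
            if self.cds_start < self.span.start or self.cds_end > self.span.end:
                raise GeneValidationError(
                    f"gene {self.gene_id}: CDS outside gene span"
                )
            if self.cds_end <= self.cds_start:
                raise GeneValidationError(
                    f"gene {self.gene_id}: empty CDS"
                )

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def tss(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end - 1

    @property
    def tts(self) -> int:
        return self.span.end - 1 if self.strand == "+" else self.span.start

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None

    def introns(self) -> list[GenomicInterval]:
        """Span minus exon union: the gaps between consecutive exons plus any
        span overhang beyond the outermost exons."""
        out: list[GenomicInterval] = []
        cursor = self.span.start
        for exon in self.exons:
            if exon.start > cursor:
                out.append(GenomicInterval(self.chrom, cursor, exon.start, self.strand))
            cursor = exon.end
        if cursor < self.span.end:
            out.append(GenomicInterval(self.chrom, cursor, self.span.end, self.strand))
        return out

    def exonic_at(self, pos: int) -> bool:
        return any(e.contains(pos) for e in self.exons)


@dataclass(frozen=True)
class LncRNALocus:
    """One lncRNA gene locus; ``anchor`` is the strand-aware 5' end."""

    lnc_id: str
    span: GenomicInterval

    def __post_init__(self) -> None:
        if self.span.strand not in ("+", "-"):
            raise GeneValidationError(
                f"lncRNA {self.lnc_id}: strand must be + or -, got {self.span.strand!r}"
            )

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def anchor(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end - 1


# --------------------------------------------------------------------------
# GTF I/O
# --------------------------------------------------------------------------

def _iter_gtf_features(path: str):
    """Yield (line_number, gffutils Feature) for every record line in a GTF."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            try:
                feat = feature_from_line(stripped)
            except Exception as exc:
                raise GtfParseError(f"{path}: malformed GTF line {lineno}: {exc}") from exc
            if feat.start is None or feat.end is None or feat.start < 1:
                raise GtfParseError(
                    f"{path}: malformed GTF line {lineno}: invalid coordinates"
                )
            yield lineno, feat


def _feature_gene_id(feat, id_attribute: str, path: str, lineno: int) -> str:
    values = feat.attributes.get(id_attribute)
    if not values:
        raise GtfParseError(
            f"{path}: line {lineno} lacks attribute {id_attribute!r}"
        )
    return values[0]


def read_gene_gtf(path: str, id_attribute: str = "gene_id") -> dict[str, GeneModel]:
    """Parse a coding-gene GTF into gene-level models keyed by gene id.

    GTF coordinates (1-based inclusive) become 0-based half-open.  Exons are
    unioned across transcripts of the same gene; CDS bounds are the min/max
    over all CDS records; genes without CDS records carry no CDS.  If a
    ``gene`` feature line declares a span, exons must lie within it;
    otherwise the span is the envelope of the gene's records.
    """
    spans: dict[str, GenomicInterval] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[int]] = {}
    envelope: dict[str, list] = {}  # gene_id -> [chrom, strand, min_start, max_end]

    for lineno, feat in _iter_gtf_features(path):
        gid = _feature_gene_id(feat, id_attribute, path, lineno)
        start0, end0 = feat.start - 1, feat.end
        strand = feat.strand if feat.strand in ("+", "-") else "."
        env = envelope.setdefault(gid, [feat.seqid, strand, start0, end0])
        if env[0] != feat.seqid:
            raise GeneValidationError(
                f"gene {gid}: records on multiple chromosomes ({env[0]}, {feat.seqid})"
            )
        env[2] = min(env[2], start0)
        env[3] = max(env[3], end0)
        if feat.featuretype == "gene":
            spans[gid] = GenomicInterval(feat.seqid, start0, end0, strand)
        elif feat.featuretype == "exon":
            exons.setdefault(gid, []).append(
                GenomicInterval(feat.seqid, start0, end0, strand)
            )
        elif feat.featuretype == "CDS":
            bounds = cds.setdefault(gid, [start0, end0])
            bounds[0] = min(bounds[0], start0)
            bounds[1] = max(bounds[1], end0)

    genes: dict[str, GeneModel] = {}
    for gid, env in envelope.items():
        chrom, strand = env[0], env[1]
        span = spans.get(gid, GenomicInterval(chrom, env[2], env[3], strand))
        gene_exons = merge_intervals(
            GenomicInterval(chrom, e.start, e.end, span.strand)
            for e in exons.get(gid, [span])
        )
        if gid in spans:
            for exon in gene_exons:
                if exon.start < span.start or exon.end > span.end:
                    raise GeneValidationError(
                        f"gene {gid}: exon [{exon.start},{exon.end}) outside declared "
                        f"span [{span.start},{span.end})"
                    )
        cds_start, cds_end = cds.get(gid, (None, None))
        genes[gid] = GeneModel(
            gene_id=gid,
            span=span,
            exons=tuple(gene_exons),
            cds_start=cds_start,
            cds_end=cds_end,
        )
    return genes


def read_lncrna_gtf(path: str, id_attribute: str = "gene_id") -> dict[str, LncRNALocus]:
    """Parse a lncRNA GTF into one locus per gene id (envelope of its records)."""
    envelope: dict[str, list] = {}
    for lineno, feat in _iter_gtf_features(path):
        gid = _feature_gene_id(feat, id_attribute, path, lineno)
        start0, end0 = feat.start - 1, feat.end
        env = envelope.setdefault(gid, [feat.seqid, feat.strand, start0, end0])
        if env[0] != feat.seqid:
            raise GeneValidationError(
                f"lncRNA {gid}: records on multiple chromosomes"
            )
        env[2] = min(env[2], start0)
        env[3] = max(env[3], end0)
    return {
        gid: LncRNALocus(gid, GenomicInterval(env[0], env[2], env[3], env[1]))
        for gid, env in envelope.items()
    }


def _gtf_line(chrom, source, ftype, start0, end0, strand, attrs) -> str:
    attr_str = " ".join(f'{k} "{v}";' for k, v in attrs)
    return f"{chrom}\t{source}\t{ftype}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attr_str}"


def write_gene_gtf(genes: Iterable[GeneModel], path: str, source: str = "lncpair") -> None:
    """Emit gene/exon/CDS records in the same GTF dialect the reader accepts."""
    with open(path, "w") as out:
        for gene in sorted(genes, key=lambda g: (g.chrom, g.span.start, g.gene_id)):
            attrs = [("gene_id", gene.gene_id)]
            out.write(
                _gtf_line(gene.chrom, source, "gene", gene.span.start, gene.span.end,
                          gene.strand, attrs) + "\n"
            )
            tx_attrs = attrs + [("transcript_id", gene.gene_id + ".t1")]
            for exon in gene.exons:
                out.write(
                    _gtf_line(gene.chrom, source, "exon", exon.start, exon.end,
                              gene.strand, tx_attrs) + "\n"
                )
            if gene.has_cds:
                out.write(
                    _gtf_line(gene.chrom, source, "CDS", gene.cds_start, gene.cds_end,
                              gene.strand, tx_attrs) + "\n"
                )


def write_lncrna_gtf(lncs: Iterable[LncRNALocus], path: str,
                     source: str = "lncpair") -> None:
    with open(path, "w") as out:
        for lnc in sorted(lncs, key=lambda l: (l.chrom, l.span.start, l.lnc_id)):
            attrs = [("gene_id", lnc.lnc_id)]
            out.write(
                _gtf_line(lnc.chrom, source, "gene", lnc.span.start, lnc.span.end,
                          lnc.strand, attrs) + "\n"
            )


# --------------------------------------------------------------------------
# Interval index
# --------------------------------------------------------------------------

class FeatureIndex:
    """Per-chromosome interval index over gene spans with nearest-gene search.

    Overlap queries go through an interval tree; nearest-neighbour queries use
    sorted span-endpoint arrays.  Answers are defined to equal a linear scan
    over all genes, with distance ties broken by lexicographically smallest
    gene id.
    """

    def __init__(self, genes: Iterable[GeneModel]):
        self._genes: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        for gene in genes:
            if gene.gene_id in self._genes:
                raise ValueError(f"duplicate gene_id {gene.gene_id!r}")
            self._genes[gene.gene_id] = gene
            by_chrom.setdefault(gene.chrom, []).append(gene)
        if not self._genes:
            raise ValueError("cannot build an index over an empty gene set")

        # sorted endpoint arrays for nearest queries
        self._starts: dict[str, tuple[np.ndarray, list[str]]] = {}
        self._ends: dict[str, tuple[np.ndarray, list[str]]] = {}
        for chrom, chrom_genes in by_chrom.items():
            tree = IntervalTree()
            for g in chrom_genes:
                tree.addi(g.span.start, g.span.end, g.gene_id)
            self._trees[chrom] = tree
            by_start = sorted(chrom_genes, key=lambda g: (g.span.start, g.gene_id))
            by_end = sorted(chrom_genes, key=lambda g: (g.span.end, g.gene_id))
            self._starts[chrom] = (
                np.array([g.span.start for g in by_start], dtype=np.int64),
                [g.gene_id for g in by_start],
            )
            self._ends[chrom] = (
                np.array([g.span.end for g in by_end], dtype=np.int64),
                [g.gene_id for g in by_end],
            )

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def get(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    def genes(self) -> Iterator[GeneModel]:
        return iter(self._genes.values())

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        """Genes whose span overlaps [start, end), sorted by gene id."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(iv.data for iv in tree.overlap(start, end))
        return [self._genes[gid] for gid in hits]

    def at(self, chrom: str, pos: int) -> list[GeneModel]:
        return self.overlapping(chrom, pos, pos + 1)

    def nearest(self, chrom: str, pos: int) -> Optional[tuple[GeneModel, int]]:
        """Gene minimizing the unsigned distance from ``pos`` to its span.

        Distance is 0 when the position lies within the span, otherwise the
        gap in bp to the nearer span edge (1 for the base just outside).
        Returns None when the chromosome holds no genes.
        """
        inside = self.at(chrom, pos)
        if inside:
            return inside[0], 0
        if chrom not in self._starts:
            return None
        candidates: list[tuple[int, str]] = []
        starts, start_ids = self._starts[chrom]
        i = int(np.searchsorted(starts, pos, side="left"))
        if i < len(starts):
            best_start = starts[i]
            j = i
            while j < len(starts) and starts[j] == best_start:
                candidates.append((int(best_start - pos), start_ids[j]))
                j += 1
        ends, end_ids = self._ends[chrom]
        i = int(np.searchsorted(ends, pos, side="right")) - 1
        if i >= 0:
            best_end = ends[i]
            j = i
            while j >= 0 and ends[j] == best_end:
                candidates.append((int(pos - best_end + 1), end_ids[j]))
                j -= 1
        if not candidates:
            return None
        dist, gid = min(candidates)
        return self._genes[gid], dist


def build_index(genes: Iterable[GeneModel] | dict[str, GeneModel]) -> FeatureIndex:
    """Build a FeatureIndex from gene models (mapping values or iterable)."""
    if isinstance(genes, dict):
        genes = genes.values()
    return FeatureIndex(genes)
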