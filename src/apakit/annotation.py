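"""Gene models, 3'UTR extension rules, and genic-region classification.

Poly(A)-tag pipelines assign cleavage sites to genes through a gene-level
model rather than per-isoform: each gene is collapsed to the union of its
exons and its most distal stop codon, and the annotated 3'UTR is extended
downstream (120 nt by default) because genuine cleavage sites frequently
fall past the annotated transcript end.  Protein-coding genes lacking an
annotated 3'UTR receive a default 338-nt 3'UTR downstream of the stop codon
(the Arabidopsis genome-wide average 3'UTR of 218 nt plus the 120-nt
extension).

Coordinates are 0-based half-open throughout (BED convention); GFF3 input
(1-based inclusive) is converted on read.
"""

from __future__ import annotations

import enum
import io
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import gffutils
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

DEFAULT_UTR3_EXTENSION_NT = 120
DEFAULT_UTR3_LENGTH_NT = 338

Interval = tuple[int, int]


class GenicRegion(enum.IntEnum):
    """Genic region labels, ordered by classification priority (low = first)."""

    UTR3 = 0
    UTR3_EXTENDED = 1
    CDS = 2
    INTRON = 3
    UTR5 = 4
    INTERGENIC = 5


@dataclass
class GeneModel:
    """A strand-aware, isoform-collapsed gene model.

    ``exons`` is the union of exons over all isoforms; ``cds_span`` the
    genomic span of all CDS segments.  ``cds_end`` is the 3' boundary of the
    most distal stop codon along the transcription direction.  ``utr3`` is
    the span of annotated three_prime_UTR features (absent for genes without
    one); ``utr3_extended`` is set by :func:`extend_three_prime_utr`.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds_span: Optional[Interval] = None
    utr3: Optional[Interval] = None
    utr3_extended: Optional[Interval] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon interval {(s, e)}")

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def cds_end(self) -> Optional[int]:
        """3' boundary coordinate of the stop codon (half-open on '+')."""
        if self.cds_span is None:
            return None
        return self.cds_span[1] if self.strand == "+" else self.cds_span[0]

    @property
    def territory(self) -> Interval:
        """Gene span united with the extended 3'UTR (lookup footprint)."""
        lo, hi = self.span
        if self.utr3_extended is not None:
            lo = min(lo, self.utr3_extended[0])
            hi = max(hi, self.utr3_extended[1])
        return (lo, hi)

    def utr3_site_length(self, position: int) -> int:
        """Distance (nt, >= 1) from the 3'UTR start (stop codon) to ``position``.

        This is the per-site 3'UTR length used by the weighted-length
        statistic. ``position`` should lie in ``utr3_extended``.
        """
        if self.utr3_extended is None:
            raise ValueError(f"{self.gene_id}: 3'UTR not extended yet")
        start, end = self.utr3_extended
        if self.strand == "+":
            return position - start + 1
        return end - position


def _contains(interval: Optional[Interval], pos: int) -> bool:
    return interval is not None and interval[0] <= pos < interval[1]


def extend_three_prime_utr(
    gene: GeneModel,
    extension_nt: int = DEFAULT_UTR3_EXTENSION_NT,
    default_utr_nt: int = DEFAULT_UTR3_LENGTH_NT,
    chrom_size: Optional[int] = None,
) -> GeneModel:
    """Set ``utr3_extended`` on a copy of ``gene``.

    An annotated 3'UTR is extended downstream (transcription direction) by
    ``extension_nt``; a gene without one receives a ``default_utr_nt``-long
    3'UTR downstream of its stop codon.  Coordinates are clipped to
    ``[0, chrom_size)`` when a chromosome size is supplied; otherwise the
    extension proceeds unclipped (below 0 it is still clipped at 0).
    """
    if extension_nt < 0:
        raise ValueError("extension_nt must be >= 0")
    if gene.cds_span is None:
        raise ValueError(f"gene {gene.gene_id} has no CDS; cannot locate stop codon")

    if gene.utr3 is not None:
        s, e = gene.utr3
        if gene.strand == "+":
            ext = (s, e + extension_nt)
        else:
            ext = (s - extension_nt, e)
    else:
        ce = gene.cds_end
        assert ce is not None
        if gene.strand == "+":
            ext = (ce, ce + default_utr_nt)
        else:
            ext = (ce - default_utr_nt, ce)

    lo = max(0, ext[0])
    hi = ext[1] if chrom_size is None else min(ext[1], chrom_size)
    if chrom_size is None and ext[1] != hi:  # pragma: no cover - defensive
        logger.warning("%s: extension unclipped (no chrom sizes)", gene.gene_id)
    if hi <= lo:
        raise ValueError(f"{gene.gene_id}: extended 3'UTR collapsed to empty interval")

    return GeneModel(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        exons=list(gene.exons),
        cds_span=gene.cds_span,
        utr3=gene.utr3,
        utr3_extended=(lo, hi),
    )


@dataclass
class GeneCatalog:
    """Collection of gene models with a strand-aware interval index."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    chrom_sizes: Optional[dict[str, int]] = None
    _index: Optional[dict[tuple[str, str], IntervalTree]] = field(
        default=None, repr=False, compare=False
    )

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise ValueError(f"duplicate gene_id {gene.gene_id}")
        self.genes[gene.gene_id] = gene
        self._index = None

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterable[GeneModel]:
        return iter(self.genes.values())

    def extend_all(
        self,
        extension_nt: int = DEFAULT_UTR3_EXTENSION_NT,
        default_utr_nt: int = DEFAULT_UTR3_LENGTH_NT,
    ) -> "GeneCatalog":
        """Apply the 3'UTR extension/default rule to every gene, in place."""
        sizes = self.chrom_sizes or {}
        for gid, g in list(self.genes.items()):
            self.genes[gid] = extend_three_prime_utr(
                g, extension_nt, default_utr_nt, chrom_size=sizes.get(g.chrom)
            )
        self._index = None
        return self

    def _build_index(self) -> dict[tuple[str, str], IntervalTree]:
        index: dict[tuple[str, str], IntervalTree] = {}
        for g in self.genes.values():
            lo, hi = g.territory
            index.setdefault((g.chrom, g.strand), IntervalTree()).addi(lo, hi, g.gene_id)
        return index

    def classify(
        self, chrom: str, strand: str, position: int
    ) -> tuple[GenicRegion, Optional[str]]:
        """Classify a genomic position into a genic region.

        When overlapping same-strand genes yield different labels the
        highest-priority label wins (UTR3 > UTR3_EXTENDED > CDS > INTRON >
        UTR5); remaining ties break on gene_id for determinism.  Positions
        covered by no same-strand gene are INTERGENIC.
        """
        if self._index is None:
            self._index = self._build_index()
        tree = self._index.get((chrom, strand))
        if tree is None:
            return (GenicRegion.INTERGENIC, None)
        best: tuple[int, str] | None = None
        for iv in tree.at(position):
            gene = self.genes[iv.data]
            label = self._classify_in_gene(gene, position)
            if label is None:
                continue
            key = (int(label), gene.gene_id)
            if best is None or key < best:
                best = key
        if best is None:
            return (GenicRegion.INTERGENIC, None)
        return (GenicRegion(best[0]), best[1])

    @staticmethod
    def _classify_in_gene(gene: GeneModel, pos: int) -> Optional[GenicRegion]:
        if _contains(gene.utr3, pos):
            return GenicRegion.UTR3
        if _contains(gene.utr3_extended, pos):
            return GenicRegion.UTR3_EXTENDED
        lo, hi = gene.span
        if not (lo <= pos < hi):
            return None
        in_exon = any(s <= pos < e for s, e in gene.exons)
        if not in_exon:
            return GenicRegion.INTRON
        if _contains(gene.cds_span, pos):
            return GenicRegion.CDS
        if gene.cds_span is not None:
            five_prime = (
                pos < gene.cds_span[0] if gene.strand == "+" else pos >= gene.cds_span[1]
            )
            if five_prime:
                return GenicRegion.UTR5
        # Exonic, non-CDS, 3' of the stop but outside the (extended) 3'UTR:
        # only reachable with clipped extensions; treat as extended UTR.
        return GenicRegion.UTR3_EXTENDED

    # ------------------------------------------------------------------ I/O

    def to_utr3_bed6(self) -> str:
        """Extended-3'UTR intervals as BED6 text."""
        lines = []
        for g in sorted(self.genes.values(), key=lambda g: (g.chrom, g.territory[0])):
            if g.utr3_extended is None:
                continue
            s, e = g.utr3_extended
            lines.append(f"{g.chrom}\t{s}\t{e}\t{g.gene_id}\t0\t{g.strand}")
        return "\n".join(lines) + "\n"

    def to_bed12(self) -> str:
        """Gene models (exon chains) as BED12 text."""
        lines = []
        for g in sorted(self.genes.values(), key=lambda g: (g.chrom, g.span[0])):
            start, end = g.span
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - start) for s, e in g.exons)
            thick = g.cds_span or (start, start)
            lines.append(
                "\t".join(
                    str(x)
                    for x in (
                        g.chrom, start, end, g.gene_id, 0, g.strand,
                        thick[0], thick[1], "0,0,0", len(g.exons), sizes, starts,
                    )
                )
            )
        return "\n".join(lines) + "\n"


def load_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>size`` table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def load_annotation(
    source: str | os.PathLike | io.TextIOBase,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> GeneCatalog:
    """Parse GFF3 into a :class:`GeneCatalog` of isoform-collapsed gene models.

    ``source`` may be a path, an open text stream, or GFF3 content itself.
    Multi-isoform genes are collapsed to the exon union and the most distal
    stop codon.  Malformed feature lines are skipped by the parser with a
    logged count; zero parsed genes is a fatal error.
    """
    if isinstance(source, io.TextIOBase):
        data, from_string = source.read(), True
    else:
        text = str(source)
        if "\n" in text or text.lstrip().startswith("##gff"):
            data, from_string = text, True
        else:
            if not os.path.exists(text):
                raise FileNotFoundError(f"annotation not found: {text}")
            data, from_string = text, False

    try:
        db = gffutils.create_db(
            data,
            dbfn=":memory:",
            from_string=from_string,
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # pragma: no cover - passthrough
        raise ValueError(f"unreadable GFF3 stream: {exc}") from exc

    catalog = GeneCatalog(chrom_sizes=chrom_sizes)
    n_skipped = 0
    for feat in db.features_of_type("gene"):
        gid = feat.id
        exons = [(f.start - 1, f.end) for f in db.children(feat, featuretype="exon")]
        cds = [(f.start - 1, f.end) for f in db.children(feat, featuretype="CDS")]
        utr3 = [
            (f.start - 1, f.end)
            for f in db.children(feat, featuretype="three_prime_UTR")
        ]
        if not exons:
            exons = [(feat.start - 1, feat.end)]
        try:
            gene = GeneModel(
                gene_id=gid,
                chrom=feat.seqid,
                strand=feat.strand,
                exons=_merge_intervals(exons),
                cds_span=(min(s for s, _ in cds), max(e for _, e in cds)) if cds else None,
                utr3=(min(s for s, _ in utr3), max(e for _, e in utr3)) if utr3 else None,
            )
            catalog.add(gene)
        except ValueError as exc:
            n_skipped += 1
            logger.warning("skipping gene %s: %s", gid, exc)
    if n_skipped:
        logger.warning("skipped %d malformed gene(s)", n_skipped)
    if len(catalog) == 0:
        raise ValueError("no genes parsed from annotation")
    return catalog


def _merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Union of possibly-overlapping intervals (isoform exon collapse)."""
    merged: list[Interval] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged
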