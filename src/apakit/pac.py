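"""Poly(A)-tag loading and poly(A)-cluster (PAC) calling.

A poly(A) tag (PAT) marks one mRNA 3'-end cleavage position at
single-nucleotide resolution.  Cleavage is microheterogeneous, so sites
within 24 nt of one another are grouped into one poly(A) cluster (PAC) by
single-linkage chaining over the sites pooled across all samples; PACs with
fewer than 10 tags summed over all samples are discarded as unreliable.
Each PAC is represented by its highest-count member site and assigned to a
gene by classifying that representative site against the gene catalog.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .annotation import GeneCatalog, GenicRegion

logger = logging.getLogger(__name__)

DEFAULT_CLUSTER_WINDOW_NT = 24
DEFAULT_MIN_PAC_TOTAL = 10

SiteKey = tuple[str, str, int]  # (chrom, strand, 0-based position)


@dataclass
class TagSet:
    """Per-sample multiset of single-nucleotide cleavage positions."""

    sample_id: str
    counts: dict[SiteKey, int] = field(default_factory=dict)

    def add(self, chrom: str, strand: str, position: int, count: int = 1) -> None:
        if count < 1:
            raise ValueError("tag count must be >= 1")
        key = (chrom, strand, int(position))
        self.counts[key] = self.counts.get(key, 0) + int(count)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class PAC:
    """A poly(A) cluster: genomic span, representative site, per-sample counts."""

    pac_id: str
    chrom: str
    strand: str
    start: int  # half-open span covering member sites
    end: int
    rep_site: int
    counts_by_sample: dict[str, int] = field(default_factory=dict)
    gene_id: Optional[str] = None
    region: Optional[GenicRegion] = None

    @property
    def total(self) -> int:
        return sum(self.counts_by_sample.values())

    def count(self, sample_id: str) -> int:
        return self.counts_by_sample.get(sample_id, 0)


def load_tags(
    path: str | os.PathLike, sample_id: str, fmt: Optional[str] = None
) -> TagSet:
    """Load a per-sample tag file into a :class:`TagSet`.

    BED: one record per tag; the cleavage site is the 3'-most base of the
    interval on '+' (``end - 1``) and the 5'-most base on '-' (``start``).
    TSV: ``chrom  position  strand  count  [sample]`` with counts copied
    verbatim (rows for other samples are ignored when a sample column is
    present).  Malformed records are skipped with a logged count.
    """
    if fmt is None:
        name = str(path).lower()
        fmt = "TSV" if name.endswith((".tsv", ".txt")) else "BED"
    fmt = fmt.upper()
    if fmt not in ("BED", "TSV"):
        raise ValueError(f"unknown tag format {fmt!r}")

    tags = TagSet(sample_id=sample_id)
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if fmt == "BED":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    strand = fields[5]
                    if strand not in "+-" or end <= start:
                        raise ValueError(line)
                    pos = end - 1 if strand == "+" else start
                    tags.add(chrom, strand, pos)
                else:
                    chrom, pos, strand = fields[0], int(fields[1]), fields[2]
                    count = int(fields[3])
                    if strand not in "+-":
                        raise ValueError(line)
                    if len(fields) >= 5 and fields[4] != sample_id:
                        continue
                    tags.add(chrom, strand, pos, count)
            except (ValueError, IndexError):
                n_bad += 1
    if n_bad:
        logger.warning("%s: skipped %d malformed record(s)", path, n_bad)
    if not tags.counts:
        raise ValueError(f"no tags loaded from {path}")
    logger.info("%s: %d tags at %d positions", sample_id, tags.total, len(tags.counts))
    return tags


def cluster_sites(
    tagsets: Sequence[TagSet], window_nt: int = DEFAULT_CLUSTER_WINDOW_NT
) -> list[PAC]:
    """Group cleavage sites within ``window_nt`` into PACs (single linkage).

    Positions are pooled over all samples per (chrom, strand) and sorted;
    adjacent positions with gap <= ``window_nt`` chain into the same PAC, so
    a cluster's end-to-end span may exceed the window.  The representative
    site is the member with the highest pooled count, ties broken toward the
    3' (downstream) end.  The result is independent of sample order.
    """
    if window_nt < 0:
        raise ValueError("window_nt must be >= 0")
    samples = [t.sample_id for t in tagsets]
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample_id among tagsets")

    # pooled and per-sample counts keyed by site
    pooled: dict[SiteKey, int] = {}
    per_sample: dict[SiteKey, dict[str, int]] = {}
    for ts in tagsets:
        for key, c in ts.counts.items():
            pooled[key] = pooled.get(key, 0) + c
            per_sample.setdefault(key, {})[ts.sample_id] = (
                per_sample.get(key, {}).get(ts.sample_id, 0) + c
            )

    by_cs: dict[tuple[str, str], list[int]] = {}
    for chrom, strand, pos in pooled:
        by_cs.setdefault((chrom, strand), []).append(pos)

    pacs: list[PAC] = []
    for (chrom, strand) in sorted(by_cs):
        positions = sorted(by_cs[(chrom, strand)])
        cluster: list[int] = [positions[0]]
        for pos in positions[1:]:
            if pos - cluster[-1] <= window_nt:
                cluster.append(pos)
            else:
                pacs.append(_make_pac(chrom, strand, cluster, pooled, per_sample, samples))
                cluster = [pos]
        pacs.append(_make_pac(chrom, strand, cluster, pooled, per_sample, samples))

    pacs.sort(key=lambda p: (p.chrom, p.start, p.strand))
    for i, p in enumerate(pacs, start=1):
        p.pac_id = f"PAC{i:05d}"
    return pacs


def _make_pac(
    chrom: str,
    strand: str,
    members: list[int],
    pooled: dict[SiteKey, int],
    per_sample: dict[SiteKey, dict[str, int]],
    samples: Sequence[str],
) -> PAC:
    # ties toward downstream: larger coordinate on '+', smaller on '-'
    def tiekey(pos: int) -> tuple[int, int]:
        return (pooled[(chrom, strand, pos)], pos if strand == "+" else -pos)

    rep = max(members, key=tiekey)
    counts = {s: 0 for s in samples}
    for pos in members:
        for s, c in per_sample.get((chrom, strand, pos), {}).items():
            counts[s] += c
    return PAC(
        pac_id="",
        chrom=chrom,
        strand=strand,
        start=min(members),
        end=max(members) + 1,
        rep_site=rep,
        counts_by_sample=counts,
    )


def filter_pacs(pacs: Iterable[PAC], min_total: int = DEFAULT_MIN_PAC_TOTAL) -> list[PAC]:
    """Keep PACs whose tag total over all samples is >= ``min_total``.

    The boundary is inclusive: a PAC with exactly ``min_total`` tags is kept
    (only totals strictly below the threshold are discarded).
    """
    pacs = list(pacs)
    kept = [p for p in pacs if p.total >= min_total]
    logger.info(
        "filter_pacs: removed %d PAC(s) below %d tags", len(pacs) - len(kept), min_total
    )
    return kept


def assign_pacs_to_genes(pacs: Iterable[PAC], catalog: GeneCatalog) -> list[PAC]:
    """Assign each PAC a gene and genic region by its representative site.

    Only the representative site is classified (a PAC spanning a boundary is
    assigned wherever its rep_site falls); PACs whose rep_site lies in no
    same-strand gene keep ``gene_id=None`` and are excluded from gene-level
    analyses downstream.
    """
    out = []
    for p in pacs:
        region, gid = catalog.classify(p.chrom, p.strand, p.rep_site)
        p.region = region
        p.gene_id = gid
        out.append(p)
    return out


def region_summary(pacs: Iterable[PAC]) -> pd.DataFrame:
    """Tally PACs and PATs per genic region (distribution-style table)."""
    rows: dict[str, dict[str, int]] = {}
    for p in pacs:
        name = p.region.name if p.region is not None else "UNASSIGNED"
        r = rows.setdefault(name, {"n_pacs": 0, "n_pats": 0})
        r["n_pacs"] += 1
        r["n_pats"] += p.total
    df = pd.DataFrame.from_dict(rows, orient="index").rename_axis("region")
    if not df.empty:
        df["pct_pacs"] = (100 * df["n_pacs"] / df["n_pacs"].sum()).round(1)
        df["pct_pats"] = (100 * df["n_pats"] / df["n_pats"].sum()).round(1)
    return df.sort_index()


def pac_table(pacs: Sequence[PAC], samples: Sequence[str]) -> pd.DataFrame:
    """PACs as a tidy table with one count column per sample."""
    rows = []
    for p in pacs:
        row = {
            "pac_id": p.pac_id,
            "chrom": p.chrom,
            "strand": p.strand,
            "start": p.start,
            "end": p.end,
            "rep_site": p.rep_site,
            "gene_id": p.gene_id if p.gene_id is not None else ".",
            "region": p.region.name if p.region is not None else ".",
        }
        for s in samples:
            row[f"count_{s}"] = p.count(s)
        rows.append(row)
    return pd.DataFrame(rows)


def pac_bed6(pacs: Sequence[PAC], sample_id: str) -> str:
    """Per-sample PAC track as BED6 (score = sample tag count)."""
    lines = [
        f"{p.chrom}\t{p.start}\t{p.end}\t{p.pac_id}\t{p.count(sample_id)}\t{p.strand}"
        for p in pacs
    ]
    return "\n".join(lines) + "\n"
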