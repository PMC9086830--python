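"""Synthetic poly(A)-tag data with known ground truth.

Generates a toy annotation plus per-sample tag BED files that emulate the
statistical structure the downstream analysis assumes: genes carrying 1-3
true poly(A) sites in (extended) 3'UTRs, negative-binomial per-replicate
gene totals split multinomially across sites by condition-level true PAU,
Gaussian positional jitter of individual cleavage events around each true
site, a designated subset of switching genes whose PAU shifts between
conditions, and a subset of differentially expressed genes.  True PAC
positions, PAU, switch/DE memberships, and weighted 3'UTR lengths are
returned as truth tables consistent with the emitted files by construction.

All randomness derives from one global seed through per-purpose substreams,
so outputs are byte-identical across runs with the same design.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .pac import TagSet

_UTR5_LEN = 50
_CDS_LEN = 300
_SPACER = 300
_SITE_MARGIN_LO = 20  # nt kept clear at the 5' end of the extended 3'UTR
_SITE_MARGIN_HI = 10


@dataclass
class SimDesign:
    """Study design of the simulation.

    Defaults mirror the analysis' reference conditions: a two-condition,
    three-replicate design of 200 genes at mean depth 100 tags per gene,
    negative-binomial dispersion 0.05, 20% of multi-PAC genes switching
    usage by delta-PAU 0.3, 10% of genes differentially expressed at
    |log2 fc| = 2, and 3-nt cleavage jitter.
    """

    n_genes: int = 200
    conditions: tuple[tuple[str, int], ...] = (("A", 3), ("B", 3))
    pac_per_gene_probs: tuple[float, float, float] = (0.40, 0.35, 0.25)
    depth_mean: float = 100.0
    nb_dispersion: float = 0.05
    frac_switch: float = 0.20
    delta_pau: float = 0.30
    frac_de: float = 0.10
    lfc_de: float = 2.0
    jitter_sd: float = 3.0
    frac_no_utr: float = 0.10
    utr_len_range: tuple[int, int] = (100, 300)
    utr_extension_nt: int = 120
    default_utr_nt: int = 338
    n_chroms: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.frac_switch, self.frac_de, self.frac_no_utr):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.depth_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("depth_mean and nb_dispersion must be positive")
        if any(n < 2 for _, n in self.conditions):
            raise ValueError("each condition needs >= 2 replicates")
        if abs(sum(self.pac_per_gene_probs) - 1.0) > 1e-9:
            raise ValueError("pac_per_gene_probs must sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return [f"{c}_{r}" for c, n in self.conditions for r in range(1, n + 1)]

    @property
    def condition_names(self) -> list[str]:
        return [c for c, _ in self.conditions]

    @property
    def min_site_separation(self) -> int:
        """True sites are spaced > cluster window + 6 sigma of jitter."""
        return int(math.ceil(24 + 6 * self.jitter_sd)) + 1


@dataclass
class TruthTables:
    """Ground truth paired with the emitted files."""

    genes: pd.DataFrame  # gene_id, chrom, strand, territory, UTR info, effects
    sites: pd.DataFrame  # gene_id, site_index, position, utr_distance, pau_<cond>
    chrom_sizes: dict[str, int]
    totals: Optional[pd.DataFrame] = None  # gene x sample drawn NB totals

    def true_pau(self, condition: str) -> pd.DataFrame:
        return self.sites[["gene_id", "site_index", "position", f"pau_{condition}"]]

    def weighted_lengths(self, condition: str) -> pd.Series:
        """True tag-weighted 3'UTR length per gene (nt) in a condition."""
        col = f"pau_{condition}"
        df = self.sites
        w = df["utr_distance"] * df[col]
        return w.groupby(df["gene_id"]).sum()

    @property
    def switch_genes(self) -> set[str]:
        return set(self.genes.loc[self.genes["is_switch"], "gene_id"])

    @property
    def de_genes(self) -> set[str]:
        return set(self.genes.loc[self.genes["is_de"], "gene_id"])


def simulate_genome(design: SimDesign) -> tuple[str, TruthTables]:
    """Lay out non-overlapping genes and true poly(A) sites; emit GFF3.

    Each gene carries a 50-nt 5'UTR, 300-nt CDS and either an annotated
    3'UTR of uniform 100-300 nt (90% of genes) or none, exercising the
    default-length rule.  True sites are placed in the (extended) 3'UTR
    with pairwise separations above ``design.min_site_separation`` so each
    true site maps to one recoverable PAC.
    """
    rng = np.random.default_rng([design.seed, 1])
    sep = design.min_site_separation
    min_ext = min(design.utr_len_range[0] + design.utr_extension_nt,
                  design.default_utr_nt)
    if _SITE_MARGIN_LO + _SITE_MARGIN_HI + 2 * sep > min_ext:
        raise ValueError(
            "site separation does not fit in the shortest extended 3'UTR; "
            "reduce jitter_sd or enlarge utr_len_range"
        )

    ks = rng.choice([1, 2, 3], size=design.n_genes, p=design.pac_per_gene_probs)
    no_utr = rng.random(design.n_genes) < design.frac_no_utr
    strands = rng.choice(["+", "-"], size=design.n_genes)
    utr_lens = rng.integers(design.utr_len_range[0], design.utr_len_range[1] + 1,
                            size=design.n_genes)
    multi = np.flatnonzero(ks >= 2)
    n_switch = int(round(design.frac_switch * multi.size))
    switch_idx = set(rng.choice(multi, size=n_switch, replace=False).tolist()) if n_switch else set()
    de_idx = set(
        rng.choice(design.n_genes, size=int(round(design.frac_de * design.n_genes)),
                   replace=False).tolist()
    )
    de_signs = {g: float(rng.choice([-1.0, 1.0])) for g in sorted(de_idx)}

    cursors = {f"chr{i + 1}": 100 for i in range(design.n_chroms)}
    gene_rows, site_rows, gff = [], [], []

    conds = design.condition_names
    for i in range(design.n_genes):
        gid = f"G{i + 1:04d}"
        chrom = f"chr{(i % design.n_chroms) + 1}"
        strand = strands[i]
        has_utr = not no_utr[i]
        L = int(utr_lens[i]) if has_utr else 0
        Lext = L + design.utr_extension_nt if has_utr else design.default_utr_nt
        body = _UTR5_LEN + _CDS_LEN + Lext
        t0 = cursors[chrom]
        t1 = t0 + body
        cursors[chrom] = t1 + _SPACER

        if strand == "+":
            utr5 = (t0, t0 + _UTR5_LEN)
            cds = (t0 + _UTR5_LEN, t0 + _UTR5_LEN + _CDS_LEN)
            stop3 = cds[1]
            utr3 = (stop3, stop3 + L) if has_utr else None
            ext = (stop3, stop3 + Lext)
            exon = (t0, utr3[1] if utr3 else cds[1])
        else:
            utr5 = (t1 - _UTR5_LEN, t1)
            cds = (t1 - _UTR5_LEN - _CDS_LEN, t1 - _UTR5_LEN)
            stop3 = cds[0]
            utr3 = (stop3 - L, stop3) if has_utr else None
            ext = (stop3 - Lext, stop3)
            exon = (utr3[0] if utr3 else cds[0], t1)

        # true sites: utr distances (1-based from the 3'UTR start)
        k = int(ks[i])
        avail = Lext - _SITE_MARGIN_LO - _SITE_MARGIN_HI - (k - 1) * sep
        picks = np.sort(rng.random(k))
        dists = [_SITE_MARGIN_LO + int(picks[j] * avail) + j * sep for j in range(k)]
        positions = [
            ext[0] + d - 1 if strand == "+" else ext[1] - d for d in dists
        ]

        pau = _draw_pau(rng, k, i in switch_idx, design)
        is_de = i in de_idx
        lfc = de_signs.get(i, 0.0) * design.lfc_de if is_de else 0.0

        gene_rows.append(
            {
                "gene_id": gid, "chrom": chrom, "strand": strand,
                "territory_start": min(t0, ext[0]), "territory_end": max(t1, ext[1]),
                "utr3_annotated": has_utr, "utr3_len": L, "utr3_ext_len": Lext,
                "n_sites": k, "is_switch": i in switch_idx,
                "is_de": is_de, "lfc": lfc,
            }
        )
        for j, (d, pos) in enumerate(zip(dists, positions)):
            row = {"gene_id": gid, "site_index": j, "position": int(pos),
                   "utr_distance": int(d)}
            for c_i, c in enumerate(conds):
                row[f"pau_{c}"] = pau[0][j] if c_i == 0 else pau[1][j]
            site_rows.append(row)

        gff.extend(_gff_features(gid, chrom, strand, t0, t1, exon, cds, utr3))

    chrom_sizes = {c: cur + 500 for c, cur in cursors.items()}
    header = ["##gff-version 3"] + [
        f"##sequence-region {c} 1 {s}" for c, s in sorted(chrom_sizes.items())
    ]
    gff3_text = "\n".join(header + gff) + "\n"
    truth = TruthTables(
        genes=pd.DataFrame(gene_rows),
        sites=pd.DataFrame(site_rows),
        chrom_sizes=chrom_sizes,
    )
    return gff3_text, truth


def _draw_pau(
    rng: np.random.Generator, k: int, switching: bool, design: SimDesign
) -> tuple[np.ndarray, np.ndarray]:
    """True PAU vectors (baseline, altered) over k sites, proximal first.

    Switching genes move ``delta_pau`` of usage between their proximal and
    distal pair in the altered condition(s); the baseline pair usage is kept
    near 50:50 so the shift stays within [0, 1] with headroom.
    """
    if switching:
        s = 1.0 - 0.2 * (k - 2)
        u = rng.uniform(0.475, 0.525)
        base = np.array([s * u, s * (1.0 - u)] + [0.2] * (k - 2))
        d = float(rng.choice([-1.0, 1.0]))
        alt = base.copy()
        alt[0] -= d * design.delta_pau
        alt[1] += d * design.delta_pau
    else:
        base = rng.dirichlet([5.0] * k)
        base = np.maximum(base, 0.1)
        base = base / base.sum()
        alt = base
    return base, alt


def _gff_features(gid, chrom, strand, t0, t1, exon, cds, utr3) -> list[str]:
    def line(ftype, s, e, attrs):
        return f"{chrom}\tsim\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}"

    mrna = f"{gid}.1"
    out = [
        line("gene", t0, t1, f"ID={gid};Name={gid}"),
        line("mRNA", t0, t1, f"ID={mrna};Parent={gid}"),
        line("exon", exon[0], exon[1], f"ID={mrna}.exon1;Parent={mrna}"),
        line("CDS", cds[0], cds[1], f"ID={mrna}.cds;Parent={mrna}"),
    ]
    if utr3 is not None:
        out.append(line("three_prime_UTR", utr3[0], utr3[1], f"ID={mrna}.utr3;Parent={mrna}"))
    return out


def simulate_tags(
    truth: TruthTables, design: SimDesign
) -> dict[str, TagSet]:
    """Draw per-sample tags for every gene; record drawn totals in truth.

    Per replicate, the gene total is NB(mean = depth * 2^lfc in altered
    conditions if DE, dispersion = nb_dispersion), split multinomially
    across the gene's sites by that condition's true PAU; each tag lands at
    its site plus rounded Gaussian jitter, clipped to the gene territory.
    """
    conds = design.condition_names
    genes = truth.genes.set_index("gene_id")
    sites_by_gene = {g: df for g, df in truth.sites.groupby("gene_id")}

    tagsets: dict[str, TagSet] = {}
    totals = pd.DataFrame(0, index=genes.index, columns=design.sample_ids)
    n = 1.0 / design.nb_dispersion

    for c_i, (cond, n_reps) in enumerate(design.conditions):
        for r in range(1, n_reps + 1):
            sample = f"{cond}_{r}"
            rng = np.random.default_rng([design.seed, 2, c_i, r])
            ts = TagSet(sample_id=sample)
            for gid, grow in genes.iterrows():
                mu = design.depth_mean
                if c_i > 0 and grow["is_de"]:
                    mu *= 2.0 ** grow["lfc"]
                total = int(rng.negative_binomial(n, n / (n + mu)))
                totals.loc[gid, sample] = total
                if total == 0:
                    continue
                sdf = sites_by_gene[gid]
                pau = sdf[f"pau_{cond}"].to_numpy()
                split = rng.multinomial(total, pau / pau.sum())
                lo = int(grow["territory_start"])
                hi = int(grow["territory_end"]) - 1
                for pos, cnt in zip(sdf["position"].to_numpy(), split):
                    if cnt == 0:
                        continue
                    jit = np.rint(rng.normal(0.0, design.jitter_sd, size=cnt)).astype(int)
                    for p in np.clip(pos + jit, lo, hi):
                        ts.add(grow["chrom"], grow["strand"], int(p))
            tagsets[sample] = ts
    truth.totals = totals
    return tagsets


def tags_to_bed(tags: TagSet) -> str:
    """One BED6 record per tag (deterministic order)."""
    lines = []
    for (chrom, strand, pos) in sorted(tags.counts):
        c = tags.counts[(chrom, strand, pos)]
        for i in range(c):
            lines.append(f"{chrom}\t{pos}\t{pos + 1}\ttag\t0\t{strand}")
    return "\n".join(lines) + "\n"


def write_fixture(out_dir: str | os.PathLike, design: SimDesign) -> dict:
    """Write a complete run-ready fixture; return a hash manifest.

    Emits the GFF3 annotation, a chrom-sizes table, one BED per sample,
    truth TSVs, and a YAML run config wired for the pipeline; the manifest
    lists the SHA-256 of every file and is stable across runs with the same
    design.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gff3_text, truth = simulate_genome(design)
    tagsets = simulate_tags(truth, design)

    files: dict[str, str] = {}

    def write(name: str, text: str) -> None:
        (out / name).write_text(text)
        files[name] = hashlib.sha256(text.encode()).hexdigest()

    write("annotation.gff3", gff3_text)
    write(
        "chrom_sizes.tsv",
        "".join(f"{c}\t{s}\n" for c, s in sorted(truth.chrom_sizes.items())),
    )
    sample_rows = []
    for cond, n_reps in design.conditions:
        for r in range(1, n_reps + 1):
            sid = f"{cond}_{r}"
            bed = f"tags_{sid}.bed"
            write(bed, tags_to_bed(tagsets[sid]))
            sample_rows.append(
                {"sample_id": sid, "path": bed, "condition": cond, "replicate": r}
            )

    write("truth_genes.tsv", truth.genes.to_csv(sep="\t", index=False))
    write("truth_sites.tsv", truth.sites.to_csv(sep="\t", index=False))
    write("truth_totals.tsv", truth.totals.to_csv(sep="\t"))

    conds = design.condition_names
    config = {
        "annotation": "annotation.gff3",
        "chrom_sizes": "chrom_sizes.tsv",
        "samples": sample_rows,
        "comparisons": [[conds[0], c] for c in conds[1:]],
        "output_dir": "results",
        "seed": design.seed,
        "thresholds": {},
    }
    write("config.yaml", yaml.safe_dump(config, sort_keys=True))

    manifest = {"design": {k: str(v) for k, v in vars(design).items()}, "files": files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
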