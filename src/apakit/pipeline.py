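"""End-to-end pairwise-comparison pipeline and its run configuration."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .annotation import load_annotation, load_chrom_sizes
from .apa_analysis import (
    detect_switch_genes,
    overlap_summary,
    shift_results_table,
    shift_summary,
    switch_events_table,
    utr_shift_test,
)
from .annotation import GenicRegion
from .diffexpr import (
    call_de,
    de_pac_apa_genes,
    nb_differential_test,
    pac_counts,
    write_gene_list,
)
from .pac import (
    assign_pacs_to_genes,
    cluster_sites,
    filter_pacs,
    load_tags,
    pac_table,
    region_summary,
)
from .quant import apa_gene_summary, compute_pau, pau_cdf_distance, pooled_condition_pau

logger = logging.getLogger(__name__)

_UTR_REGIONS = {GenicRegion.UTR3.name, GenicRegion.UTR3_EXTENDED.name}


@dataclass
class Thresholds:
    """Analysis thresholds; defaults are the pipeline's reference values."""

    window_nt: int = 24
    min_pac_total: int = 10
    min_gene_reads: int = 10
    min_delta_pau: float = 0.1
    alpha_de: float = 0.05
    alpha_utr: float = 0.01
    utr_extension: int = 120
    default_utr: int = 338


@dataclass
class SampleSpec:
    sample_id: str
    path: str
    condition: str
    replicate: int
    format: Optional[str] = None


@dataclass
class RunConfig:
    annotation: str
    samples: list[SampleSpec]
    comparisons: list[tuple[str, str]]
    output_dir: str
    thresholds: Thresholds = field(default_factory=Thresholds)
    chrom_sizes: Optional[str] = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        base = Path(path).parent
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thr = Thresholds(**(raw.get("thresholds") or {}))
        samples = [
            SampleSpec(
                sample_id=s["sample_id"],
                path=str(base / s["path"]),
                condition=s["condition"],
                replicate=int(s["replicate"]),
                format=s.get("format"),
            )
            for s in raw["samples"]
        ]
        return cls(
            annotation=str(base / raw["annotation"]),
            samples=samples,
            comparisons=[tuple(c) for c in raw["comparisons"]],
            output_dir=str(base / raw.get("output_dir", "results")),
            thresholds=thr,
            chrom_sizes=str(base / raw["chrom_sizes"]) if raw.get("chrom_sizes") else None,
            seed=int(raw.get("seed", 0)),
        )

    def validate(self) -> None:
        for s in self.samples:
            if not os.path.exists(s.path):
                raise FileNotFoundError(f"sample file missing: {s.path}")
        if not os.path.exists(self.annotation):
            raise FileNotFoundError(f"annotation missing: {self.annotation}")
        reps = self.replicate_map
        for a, b in self.comparisons:
            for cond in (a, b):
                if len(reps.get(cond, [])) < 2:
                    raise ValueError(f"condition {cond!r} needs >= 2 replicates")

    @property
    def replicate_map(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in self.samples:
            out.setdefault(s.condition, []).append(s.sample_id)
        return out


class StageError(RuntimeError):
    """Failure of a named pipeline stage."""

    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {exc}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Run annotation -> PAC -> PAU -> differential -> APA analytics.

    Writes every module's tables under ``config.output_dir`` plus a
    ``summary.json`` with the headline quantities (APA ratios, K-S D per
    pair, DE / switch / UTR-shift counts, overlap percentages) and a run
    log recording version, seed and thresholds.  Returns the summary dict.
    """
    config.validate()
    thr = config.thresholds
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_log(outdir / "run.log")
    logger.info("apakit %s | seed=%d | thresholds=%s", __version__, config.seed, thr)

    stage = "annotation"
    try:
        sizes = load_chrom_sizes(config.chrom_sizes) if config.chrom_sizes else None
        catalog = load_annotation(config.annotation, chrom_sizes=sizes)
        catalog.extend_all(thr.utr_extension, thr.default_utr)

        stage = "pac"
        tagsets = [load_tags(s.path, s.sample_id, s.format) for s in config.samples]
        pacs = cluster_sites(tagsets, window_nt=thr.window_nt)
        pacs = filter_pacs(pacs, min_total=thr.min_pac_total)
        pacs = assign_pacs_to_genes(pacs, catalog)
        samples = [s.sample_id for s in config.samples]
        pac_table(pacs, samples).to_csv(outdir / "pacs.tsv", sep="\t", index=False)
        region_summary(pacs).to_csv(outdir / "region_summary.tsv", sep="\t")

        stage = "quant"
        replicate_map = config.replicate_map
        pau = compute_pau(pacs, replicate_map)
        pau.pau_condition.to_csv(outdir / "pau_condition.tsv", sep="\t")
        apa = apa_gene_summary(pacs, replicate_map)
        apa.to_csv(outdir / "apa_summary.tsv", sep="\t")

        design = {s.sample_id: s.condition for s in config.samples}
        region_of = {p.pac_id: p.region.name for p in pacs if p.region is not None}
        utr_pacs_by_gene = _utr_pacs_by_gene(pacs, catalog)

        summary: dict = {
            "version": __version__,
            "seed": config.seed,
            "n_pacs": len(pacs),
            "apa_ratio_pct": {
                str(scope): int(apa.loc[scope, "apa_ratio_pct"]) for scope in apa.index
            },
            "comparisons": {},
        }

        for cond_a, cond_b in config.comparisons:
            stage = f"diffexpr[{cond_a}-vs-{cond_b}]"
            pair = f"{cond_a}_vs_{cond_b}"
            pdir = outdir / pair
            pdir.mkdir(exist_ok=True)

            cm_pac = pac_counts(pacs, design, by="pac")
            res_pac = nb_differential_test(cm_pac, cond_a, cond_b)
            res_pac.to_csv(pdir / "de_pacs.tsv", sep="\t")
            de_pacs = call_de(res_pac, alpha=thr.alpha_de)

            cm_gene = pac_counts(pacs, design, by="gene")
            res_gene = nb_differential_test(cm_gene, cond_a, cond_b)
            res_gene.to_csv(pdir / "de_genes.tsv", sep="\t")
            de_genes = call_de(res_gene, alpha=thr.alpha_de)
            write_gene_list(de_genes, str(pdir / "de_gene_list.txt"))
            apa_de_genes = de_pac_apa_genes(de_pacs, pacs)

            stage = f"apa_analysis[{cond_a}-vs-{cond_b}]"
            events = detect_switch_genes(
                pau, cond_a, cond_b, de_pacs,
                min_gene_reads=thr.min_gene_reads, min_delta=thr.min_delta_pau,
            )
            switch_events_table(events).to_csv(
                pdir / "switch_events.tsv", sep="\t", index=False
            )
            switch_genes = {e.gene_id for e in events}

            shift_results = []
            for gene_id, gene_pacs in utr_pacs_by_gene.items():
                lengths = [l for l, _ in gene_pacs]
                ids = [pid for _, pid in gene_pacs]
                counts_a = _pooled_counts(pacs, ids, replicate_map[cond_a])
                counts_b = _pooled_counts(pacs, ids, replicate_map[cond_b])
                shift_results.append(
                    utr_shift_test(gene_id, lengths, counts_a, counts_b,
                                   alpha=thr.alpha_utr)
                )
            shift_results_table(shift_results).to_csv(
                pdir / "utr_shift.tsv", sep="\t", index=False
            )

            ks = pau_cdf_distance(
                pooled_condition_pau(pau, cond_a),
                pooled_condition_pau(pau, cond_b),
            )
            ov_de = overlap_summary(de_genes, apa_de_genes)
            ov_sw = overlap_summary(switch_genes, de_genes)
            pair_summary = {
                "ks_d": round(ks.d_stat, 4),
                "ks_p": ks.p_value,
                "n_de_pacs": len(de_pacs),
                "n_de_genes": len(de_genes),
                "n_de_pac_apa_genes": len(apa_de_genes),
                "n_switch_genes": len(switch_genes),
                "utr_shift": shift_summary(shift_results),
                "overlap_de_vs_apa": ov_de,
                "overlap_switch_vs_de": ov_sw,
            }
            with open(pdir / "overlap.json", "w") as fh:
                json.dump({"de_vs_apa": ov_de, "switch_vs_de": ov_sw}, fh, indent=2)
            summary["comparisons"][pair] = pair_summary

        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return summary
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc


def _utr_pacs_by_gene(pacs, catalog) -> dict[str, list[tuple[int, str]]]:
    """(3'UTR length, pac_id) per gene for PACs in (extended) 3'UTRs."""
    out: dict[str, list[tuple[int, str]]] = {}
    for p in pacs:
        if p.gene_id is None or p.region is None:
            continue
        if p.region.name not in _UTR_REGIONS:
            continue
        gene = catalog.genes[p.gene_id]
        out.setdefault(p.gene_id, []).append(
            (gene.utr3_site_length(p.rep_site), p.pac_id)
        )
    return {g: v for g, v in out.items() if len(v) >= 2}


def _pooled_counts(pacs, pac_ids: list[str], samples: list[str]) -> list[int]:
    by_id = {p.pac_id: p for p in pacs}
    return [sum(by_id[pid].count(s) for s in samples) for pid in pac_ids]


def _setup_log(path: Path) -> None:
    root = logging.getLogger("apakit")
    root.setLevel(logging.INFO)
    if not any(
        isinstance(h, logging.FileHandler) and h.baseFilename == str(path)
        for h in root.handlers
    ):
        root.addHandler(logging.FileHandler(path))
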