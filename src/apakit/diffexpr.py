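"""Two-condition negative-binomial differential testing of PAC/gene counts.

A self-contained, desk-scale differential test in the median-of-ratios /
NB-Wald family: per-sample size factors by the median-of-ratios estimator,
per-feature NB dispersion by method of moments pooled across the two
groups, and a Wald test on the log2 fold change of (pseudo-count-moderated)
group means.  Raw method-of-moments dispersions at 3-vs-3 replication are
noisy enough to make a plain normal Wald reference anticonservative, so the
per-feature dispersion is floored at the ensemble median dispersion — a
minimal moderation (no mean-dispersion trend fitting) under which the
normal reference is well calibrated at the default design.  Benjamini-
Hochberg adjustment controls FDR; features are called at adjusted p < alpha
(strict inequality).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pac import PAC

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
_MIN_DISPERSION = 1e-8
_PSEUDO_MEAN = 0.5


@dataclass
class CountMatrix:
    """Integer feature-by-sample counts with a sample -> condition design."""

    counts: pd.DataFrame
    design: Mapping[str, str]

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.design)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.design[s] == condition]


def pac_counts(
    pacs: Sequence[PAC], design: Mapping[str, str], by: str = "pac"
) -> CountMatrix:
    """Build a CountMatrix from gene-assigned PACs.

    ``by="pac"`` keeps one row per PAC; ``by="gene"`` sums all PATs of a
    gene into one row, representing gene expression level.
    """
    samples = list(design)
    assigned = [p for p in pacs if p.gene_id is not None]
    rows = {p.pac_id: [p.count(s) for s in samples] for p in assigned}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    if by == "gene":
        gene_of = pd.Series({p.pac_id: p.gene_id for p in assigned})
        df = df.groupby(gene_of).sum()
    elif by != "pac":
        raise ValueError("by must be 'pac' or 'gene'")
    return CountMatrix(counts=df, design=design)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    Features with a zero in any sample are excluded from the reference
    (their geometric mean would vanish); if no feature is nonzero in all
    samples, total-count factors scaled to geometric mean 1 are used with a
    warning.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if all_nonzero.any():
        ref = mat[all_nonzero]
        log_geomean = np.log(ref).mean(axis=1)
        factors = np.exp(np.median(np.log(ref) - log_geomean[:, None], axis=0))
    else:
        logger.warning("no feature nonzero in all samples; using library-size factors")
        libsize = mat.sum(axis=0)
        if (libsize <= 0).any():
            raise ValueError("sample with zero total count")
        factors = libsize / np.exp(np.mean(np.log(libsize)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


@dataclass
class NBTestOptions:
    """Tuning knobs of the NB Wald test (defaults match the pipeline)."""

    pseudo_mean: float = _PSEUDO_MEAN
    min_dispersion: float = _MIN_DISPERSION
    moderate_dispersion: bool = True  # floor at ensemble median dispersion


def nb_differential_test(
    cm: CountMatrix,
    condition_a: str,
    condition_b: str,
    options: Optional[NBTestOptions] = None,
) -> pd.DataFrame:
    """Wald test of log2 fold change (B vs A) per feature.

    Counts are scaled by per-pair size factors; per-feature dispersion is
    method-of-moments on the pooled within-group variance, floored at the
    ensemble median (see module docstring); the Wald statistic divides the
    moderated log2 fold change by its delta-method standard error and is
    referred to the standard normal.  All-zero features get p = 1, lfc = 0.

    Returns a frame indexed by feature with columns ``base_mean``,
    ``log2_fold_change``, ``p_value``, ``padj``, ``significant``.
    """
    opt = options or NBTestOptions()
    sa = cm.samples_of(condition_a)
    sb = cm.samples_of(condition_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each compared condition needs >= 2 replicates")

    sub = cm.counts[sa + sb]
    sf = size_factors(sub)
    norm = sub / sf
    A = norm[sa].to_numpy(dtype=float)
    B = norm[sb].to_numpy(dtype=float)
    nA, nB = A.shape[1], B.shape[1]

    mA, mB = A.mean(axis=1), B.mean(axis=1)
    vA = A.var(axis=1, ddof=1)
    vB = B.var(axis=1, ddof=1)
    v_pool = ((nA - 1) * vA + (nB - 1) * vB) / (nA + nB - 2)
    mu = (A.sum(axis=1) + B.sum(axis=1)) / (nA + nB)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mu > 0, (v_pool - mu) / mu**2, 0.0)
    disp = np.maximum(disp, 0.0)
    if opt.moderate_dispersion and (mu > 0).any():
        disp = np.maximum(disp, np.median(disp[mu > 0]))
    disp = np.maximum(disp, opt.min_dispersion)

    pm = opt.pseudo_mean
    lfc = np.log2((mB + pm) / (mA + pm))
    ln2sq = np.log(2.0) ** 2
    var_mean_A = (mA + disp * mA**2) / nA
    var_mean_B = (mB + disp * mB**2) / nB
    se = np.sqrt(
        var_mean_A / (ln2sq * (mA + pm) ** 2) + var_mean_B / (ln2sq * (mB + pm) ** 2)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    dead = (mA == 0) & (mB == 0)
    lfc[dead] = 0.0
    p[dead] = 1.0

    padj = adjust_pvalues_bh(p)
    res = pd.DataFrame(
        {
            "base_mean": mu,
            "log2_fold_change": lfc,
            "p_value": p,
            "padj": padj,
            "significant": padj < DEFAULT_ALPHA,
        },
        index=sub.index.rename("feature_id"),
    )
    return res


def adjust_pvalues_bh(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN inputs propagate NaN and are excluded from the number of tests m;
    values outside [0, 1] raise.
    """
    p = np.asarray(list(p_values), dtype=float)
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    pf = p[finite]
    m = pf.size
    if m == 0:
        return out
    order = np.argsort(pf, kind="mergesort")
    ranked = pf[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    vals = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = vals
    out[finite] = res
    return out


def call_de(results: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> set[str]:
    """Features with adjusted p strictly below ``alpha``."""
    sig = results["padj"] < alpha
    return set(results.index[sig.fillna(False)])


def de_pac_apa_genes(
    de_pacs: set[str], pacs: Sequence[PAC]
) -> set[str]:
    """Genes with >= 2 PACs of which >= 1 is differentially expressed.

    Single-PAC genes are never APA genes even if their PAC is significant.
    """
    pacs_per_gene: dict[str, list[str]] = {}
    for p in pacs:
        if p.gene_id is not None:
            pacs_per_gene.setdefault(p.gene_id, []).append(p.pac_id)
    return {
        g
        for g, pids in pacs_per_gene.items()
        if len(pids) >= 2 and any(pid in de_pacs for pid in pids)
    }


def write_gene_list(genes: Iterable[str], path: str) -> None:
    """Plain one-id-per-line gene list (for external GO enrichment tools)."""
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")
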