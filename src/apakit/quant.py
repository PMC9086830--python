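"""Poly(A)-site usage (PAU) quantification and distribution comparison.

PAU of a PAC in a sample is the ratio of its tag count to the gene's total
tag count in that sample.  Condition-level PAU is by default the arithmetic
mean of per-replicate PAU over replicates where the gene is expressed
(a pooled count-ratio alternative is available).  PAU distributions between
conditions are compared through folded empirical CDFs ("mountain plots",
min(F, 1-F)) and the two-sample Kolmogorov-Smirnov statistic; note the K-S
D statistic is invariant to any strictly monotone transform of the values,
so the log transform used for plotting does not affect D.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pac import PAC


@dataclass
class PAUMatrix:
    """Per-gene, per-PAC usage fractions at replicate and condition level.

    ``pau_replicate`` / ``pau_condition``: rows indexed by (gene_id, pac_id),
    columns samples / conditions, values in [0, 1] (NaN where the gene has
    zero total).  ``gene_totals_*``: per-gene tag totals.
    """

    pau_replicate: pd.DataFrame
    pau_condition: pd.DataFrame
    gene_totals_replicate: pd.DataFrame
    gene_totals_condition: pd.DataFrame
    replicate_map: Mapping[str, Sequence[str]]

    def gene_pacs(self, gene_id: str) -> list[str]:
        return list(self.pau_condition.loc[gene_id].index)


@dataclass
class KSResult:
    """Two-sample Kolmogorov-Smirnov comparison of PAU distributions."""

    d_stat: float
    p_value: float
    n_a: int
    n_b: int


def pac_count_frame(pacs: Sequence[PAC], samples: Sequence[str]) -> pd.DataFrame:
    """Counts of gene-assigned PACs as a (gene_id, pac_id) x sample frame."""
    assigned = [p for p in pacs if p.gene_id is not None]
    if not assigned:
        raise ValueError("no gene-assigned PACs")
    index = pd.MultiIndex.from_tuples(
        [(p.gene_id, p.pac_id) for p in assigned], names=["gene_id", "pac_id"]
    )
    data = {s: [p.count(s) for p in assigned] for s in samples}
    return pd.DataFrame(data, index=index).sort_index()


def compute_pau(
    pacs: Sequence[PAC],
    replicate_map: Mapping[str, Sequence[str]],
    condition_method: str = "mean",
) -> PAUMatrix:
    """Compute replicate- and condition-level PAU from gene-assigned PACs.

    ``replicate_map`` maps condition -> replicate sample ids.  With
    ``condition_method="mean"`` (default) condition PAU is the mean of
    per-replicate PAU over replicates where the gene has nonzero total; with
    ``"pooled"`` it is the ratio of summed counts.  Genes with zero total in
    every replicate of a condition have NaN PAU there.
    """
    for cond, reps in replicate_map.items():
        if len(reps) == 0:
            raise ValueError(f"empty replicate group for condition {cond!r}")
    if condition_method not in ("mean", "pooled"):
        raise ValueError("condition_method must be 'mean' or 'pooled'")

    samples = [s for reps in replicate_map.values() for s in reps]
    counts = pac_count_frame(pacs, samples)
    totals_rep = counts.groupby(level="gene_id").transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        pau_rep = counts / totals_rep
    pau_rep = pau_rep.where(totals_rep > 0)

    pau_cond = {}
    for cond, reps in replicate_map.items():
        if condition_method == "mean":
            pau_cond[cond] = pau_rep[list(reps)].mean(axis=1)
        else:
            pooled = counts[list(reps)].sum(axis=1)
            pooled_tot = pooled.groupby(level="gene_id").transform("sum")
            pau_cond[cond] = (pooled / pooled_tot).where(pooled_tot > 0)
    pau_cond_df = pd.DataFrame(pau_cond)

    gene_totals_rep = counts.groupby(level="gene_id").sum()
    gene_totals_cond = pd.DataFrame(
        {c: gene_totals_rep[list(r)].sum(axis=1) for c, r in replicate_map.items()}
    )
    return PAUMatrix(
        pau_replicate=pau_rep,
        pau_condition=pau_cond_df,
        gene_totals_replicate=gene_totals_rep,
        gene_totals_condition=gene_totals_cond,
        replicate_map=dict(replicate_map),
    )


def apa_ratio_pct(n_apa: int, n_genes: int) -> int:
    """APA-gene percentage, rounded to integer as reported (e.g. 63)."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    return int(round(100.0 * n_apa / n_genes))


def apa_gene_summary(
    pacs: Sequence[PAC],
    replicate_map: Optional[Mapping[str, Sequence[str]]] = None,
) -> pd.DataFrame:
    """Count genes by PAC number (1/2/3/>=4 bins) and the APA-gene ratio.

    Scope "all" uses every gene-assigned PAC; with a ``replicate_map`` one
    row per condition is added where a PAC counts as expressed if its tag
    total over that condition's replicates is >= 1.  The APA ratio is genes
    with >= 2 expressed PACs over genes with >= 1 expressed PAC.
    """
    assigned = [p for p in pacs if p.gene_id is not None]

    def summarize(scope: str, n_pacs_per_gene: Mapping[str, int]) -> dict:
        ks = np.array(list(n_pacs_per_gene.values()))
        ks = ks[ks >= 1]
        n_genes = len(ks)
        n_apa = int((ks >= 2).sum())
        return {
            "scope": scope,
            "genes_1pac": int((ks == 1).sum()),
            "genes_2pac": int((ks == 2).sum()),
            "genes_3pac": int((ks == 3).sum()),
            "genes_4plus": int((ks >= 4).sum()),
            "n_genes": n_genes,
            "n_apa_genes": n_apa,
            "apa_ratio": n_apa / n_genes if n_genes else float("nan"),
            "apa_ratio_pct": apa_ratio_pct(n_apa, n_genes) if n_genes else 0,
        }

    rows = []
    global_counts: dict[str, int] = {}
    for p in assigned:
        if p.total >= 1:
            global_counts[p.gene_id] = global_counts.get(p.gene_id, 0) + 1
    rows.append(summarize("all", global_counts))

    if replicate_map is not None:
        for cond, reps in replicate_map.items():
            counts: dict[str, int] = {}
            for p in assigned:
                if sum(p.count(s) for s in reps) >= 1:
                    counts[p.gene_id] = counts.get(p.gene_id, 0) + 1
            rows.append(summarize(cond, counts))
    return pd.DataFrame(rows).set_index("scope")


def pau_cdf_distance(
    pau_a: Sequence[float], pau_b: Sequence[float], log_transform: bool = True
) -> KSResult:
    """Two-sample K-S test between two pooled PAU value sets.

    D is computed on the (optionally log-transformed) values; because D is
    invariant under strictly monotone transforms, the transform choice only
    matters for plotting.  The invariance is asserted at run time.
    """
    a = np.asarray(pau_a, dtype=float)
    b = np.asarray(pau_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty PAU vector")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("PAU values for CDF comparison must be in (0, 1]")
    d_raw = stats.ks_2samp(a, b, method="asymp")
    if log_transform:
        res = stats.ks_2samp(np.log2(a), np.log2(b), method="asymp")
        assert np.isclose(res.statistic, d_raw.statistic), "K-S D not transform-invariant"
    else:
        res = d_raw
    return KSResult(
        d_stat=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=a.size,
        n_b=b.size,
    )


def pooled_condition_pau(
    pau: PAUMatrix, condition: str, region_of: Optional[Mapping[str, str]] = None,
    regions: Optional[set[str]] = None,
) -> np.ndarray:
    """Pool a condition's per-PAC PAU values (for CDF/K-S comparison).

    Zero-PAU PACs (expressed elsewhere but absent in this condition) are
    excluded so every pooled value lies in (0, 1].  ``region_of`` plus
    ``regions`` optionally restricts pooling to PACs in given genic regions.
    """
    s = pau.pau_condition[condition].dropna()
    if region_of is not None and regions is not None:
        keep = [region_of.get(pac) in regions for _, pac in s.index]
        s = s[np.asarray(keep, dtype=bool)]
    vals = s.to_numpy()
    return vals[vals > 0]


def mountain_plot_data(values: Sequence[float], log_base: float = 2.0) -> pd.DataFrame:
    """Folded ECDF points for a mountain plot.

    Returns a frame with columns ``log_pau`` (log of the value, base
    ``log_base``), ``ecdf`` (right-continuous F at the point) and ``folded``
    (min(F, 1-F)); points sorted by value.  The fold apex sits at the median.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("no values")
    if (v <= 0).any():
        raise ValueError("values must be in (0, 1]")
    ecdf = np.arange(1, v.size + 1) / v.size
    folded = np.minimum(ecdf, 1.0 - ecdf)
    return pd.DataFrame(
        {"log_pau": np.log(v) / np.log(log_base), "ecdf": ecdf, "folded": folded}
    )
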