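"""APA switch-gene calling and 3'UTR length dynamics.

Switch genes between two conditions are genes passing three criteria:
(1) total tag count > 10 for the gene in each compared condition,
(2) some PAC shifts usage by |PAU_a - PAU_b| >= 0.1, and
(3) at least one of the gene's PACs is differentially expressed.

The weighted 3'UTR length of a gene is the tag-count-weighted mean of its
sites' 3'UTR lengths, sum(a_i * b_i) / sum(b_i), where a_i is the distance
from the stop codon (3'UTR start) to site i and b_i its tag count — the
k-site generalization of the two-site formula (a1*b1 + a2*b2)/(b1 + b2).
A gene's 3'UTR is called significantly lengthened or shortened between
conditions when the proximal-versus-distal count composition differs at
p < 0.01 (Fisher's exact test on the 2x2 table for two sites; chi-square on
the k x 2 table otherwise, with an exact conditional enumeration fallback
at low expected counts) and the weighted length moves accordingly.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quant import PAUMatrix

DEFAULT_MIN_GENE_READS = 10
DEFAULT_MIN_DELTA_PAU = 0.1
DEFAULT_UTR_ALPHA = 0.01


@dataclass
class SwitchEvent:
    """Outcome of the three-criterion switch test for one gene."""

    gene_id: str
    condition_pair: tuple[str, str]
    max_shift_pac: Optional[str]
    delta_pau: float  # signed shift (b - a) of the max-|shift| PAC
    total_reads_ok: bool
    delta_ok: bool
    de_pac_ok: bool

    @property
    def is_switch(self) -> bool:
        return self.total_reads_ok and self.delta_ok and self.de_pac_ok


class ShiftCall(enum.Enum):
    LENGTHENED = "LENGTHENED"
    SHORTENED = "SHORTENED"
    NS = "NS"


@dataclass
class UTRShiftResult:
    """Weighted 3'UTR lengths in two conditions and the shift call."""

    gene_id: str
    weighted_len_a: Optional[float]
    weighted_len_b: Optional[float]
    p_value: float
    call: ShiftCall
    reason: Optional[str] = None


def detect_switch_genes(
    pau: PAUMatrix,
    cond_a: str,
    cond_b: str,
    de_pac_set: set[str],
    min_gene_reads: int = DEFAULT_MIN_GENE_READS,
    min_delta: float = DEFAULT_MIN_DELTA_PAU,
    report_all: bool = False,
) -> list[SwitchEvent]:
    """Call APA switch genes between two conditions.

    The read-count criterion is enforced in each condition separately
    (summed over its replicates, strictly > ``min_gene_reads``).  By default
    only passing genes are returned; ``report_all`` keeps every evaluated
    gene with its per-criterion booleans.
    """
    if de_pac_set is None:
        raise ValueError("de_pac_set is required (run the differential test first)")
    totals = pau.gene_totals_condition
    pc = pau.pau_condition
    events: list[SwitchEvent] = []
    for gene_id in totals.index:
        tot_a = int(totals.loc[gene_id, cond_a])
        tot_b = int(totals.loc[gene_id, cond_b])
        total_ok = tot_a > min_gene_reads and tot_b > min_gene_reads
        sub = pc.loc[gene_id]
        delta = (sub[cond_b] - sub[cond_a]).dropna()
        if delta.empty:
            ev = SwitchEvent(gene_id, (cond_a, cond_b), None, float("nan"),
                             total_ok, False, False)
        else:
            top = delta.abs().idxmax()
            d = float(delta.loc[top])
            de_ok = any(pac in de_pac_set for pac in sub.index)
            ev = SwitchEvent(
                gene_id, (cond_a, cond_b), str(top), d,
                total_ok, abs(d) >= min_delta, de_ok,
            )
        if report_all or ev.is_switch:
            events.append(ev)
    return events


def weighted_utr_length(
    site_lengths: Sequence[float], counts: Sequence[float]
) -> Optional[float]:
    """Tag-count-weighted mean 3'UTR length, sum(a_i b_i) / sum(b_i).

    Returns None when the total count is zero (length undefined).
    """
    a = np.asarray(site_lengths, dtype=float)
    b = np.asarray(counts, dtype=float)
    if a.size != b.size or a.size == 0:
        raise ValueError("site_lengths and counts must have equal size >= 1")
    if (b < 0).any():
        raise ValueError("counts must be non-negative")
    total = b.sum()
    if total == 0:
        return None
    return float((a * b).sum() / total)


def _exact_kx2_pvalue(table: np.ndarray) -> float:
    """Exact conditional test p-value for a k x 2 table with fixed margins.

    Enumerates the multivariate hypergeometric distribution of column 1
    given the row totals and sums probabilities <= that of the observed
    table (the standard two-sided exact-test ordering, reducing to Fisher's
    exact test at k = 2).
    """
    row = table.sum(axis=1).astype(int)
    colA = int(table[:, 0].sum())
    N = int(table.sum())
    log_denom = _logC(N, colA)

    def log_prob(xs: Sequence[int]) -> float:
        return sum(_logC(r, x) for r, x in zip(row, xs)) - log_denom

    obs_lp = log_prob(table[:, 0].astype(int))
    total = 0.0
    k = len(row)

    def rec(i: int, remaining: int, acc: float) -> None:
        nonlocal total
        if i == k - 1:
            if 0 <= remaining <= row[i]:
                lp_full = acc + _logC(row[i], remaining) - log_denom
                if lp_full <= obs_lp + 1e-9:
                    total += math.exp(lp_full)
            return
        lo = max(0, remaining - int(row[i + 1:].sum()))
        hi = min(row[i], remaining)
        for x in range(lo, hi + 1):
            rec(i + 1, remaining - x, acc + _logC(row[i], x))

    rec(0, colA, 0.0)
    return min(total, 1.0)


def _logC(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


_EXACT_FALLBACK_MAX_N = 500


def utr_shift_test(
    gene_id: str,
    site_lengths: Sequence[float],
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    alpha: float = DEFAULT_UTR_ALPHA,
) -> UTRShiftResult:
    """Test whether a gene's 3'UTR is lengthened or shortened in B vs A.

    ``site_lengths`` are the per-PAC 3'UTR lengths (distance from the stop
    codon), ``counts_a``/``counts_b`` the replicate-pooled tag counts per
    PAC in each condition, in matching order (proximal-to-distal ordering is
    applied internally).  With two sites the composition test is Fisher's
    exact test; with more, chi-square on the k x 2 table, falling back to an
    exact conditional enumeration when any expected cell is < 5 and the
    table total is modest.  A significant gene (p < ``alpha``) is called
    LENGTHENED when the weighted length in B exceeds that in A, SHORTENED
    when smaller.
    """
    a = np.asarray(site_lengths, dtype=float)
    ca = np.asarray(counts_a, dtype=float)
    cb = np.asarray(counts_b, dtype=float)
    if not (a.size == ca.size == cb.size):
        raise ValueError("length/count vectors must align")

    order = np.argsort(a, kind="mergesort")  # proximal -> distal
    a, ca, cb = a[order], ca[order], cb[order]
    len_a = weighted_utr_length(a, ca)
    len_b = weighted_utr_length(a, cb)

    if a.size < 2:
        return UTRShiftResult(gene_id, len_a, len_b, 1.0, ShiftCall.NS,
                              reason="fewer than 2 3'UTR PACs")
    if len_a is None or len_b is None:
        return UTRShiftResult(gene_id, len_a, len_b, 1.0, ShiftCall.NS,
                              reason="zero total count in a condition")

    used = (ca + cb) > 0
    table = np.column_stack([ca, cb])[used]
    if table.shape[0] < 2:
        return UTRShiftResult(gene_id, len_a, len_b, 1.0, ShiftCall.NS,
                              reason="fewer than 2 PACs with tags")

    if table.shape[0] == 2:
        _, p = stats.fisher_exact(np.round(table).astype(int), alternative="two-sided")
    else:
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any() and table.sum() <= _EXACT_FALLBACK_MAX_N:
            p = _exact_kx2_pvalue(np.round(table).astype(int))
        else:
            _, p, _, _ = stats.chi2_contingency(table)

    if p < alpha:
        call = ShiftCall.LENGTHENED if len_b > len_a else (
            ShiftCall.SHORTENED if len_b < len_a else ShiftCall.NS
        )
    else:
        call = ShiftCall.NS
    return UTRShiftResult(gene_id, len_a, len_b, float(p), call)


def shift_summary(results: Sequence[UTRShiftResult]) -> dict:
    """Per-comparison tally of significant 3'UTR shifts.

    Reports counts of lengthened/shortened genes, the proximal:distal
    preference ratio (shortened over lengthened), and the median weighted-
    length change (B - A, nt) within each significant class.
    """
    lengthened = [r for r in results if r.call is ShiftCall.LENGTHENED]
    shortened = [r for r in results if r.call is ShiftCall.SHORTENED]

    def median_delta(rs: list[UTRShiftResult]) -> Optional[float]:
        if not rs:
            return None
        return float(np.median([r.weighted_len_b - r.weighted_len_a for r in rs]))

    n_len, n_short = len(lengthened), len(shortened)
    return {
        "n_tested": len(results),
        "n_lengthened": n_len,
        "n_shortened": n_short,
        "proximal_to_distal_ratio": (n_short / n_len) if n_len else None,
        "median_delta_lengthened_nt": median_delta(lengthened),
        "median_delta_shortened_nt": median_delta(shortened),
    }


def overlap_summary(set_a: set, set_b: set) -> dict:
    """Venn-style overlap of two gene sets with integer percentages."""
    inter = set_a & set_b
    return {
        "a_only": len(set_a - set_b),
        "b_only": len(set_b - set_a),
        "intersection": len(inter),
        "pct_a_in_b": int(round(100 * len(inter) / len(set_a))) if set_a else 0,
        "pct_b_in_a": int(round(100 * len(inter) / len(set_b))) if set_b else 0,
    }


def length_expression_correlation(
    delta_weighted_len: Mapping[str, float], gene_lfc: Mapping[str, float]
) -> dict:
    """Correlation between 3'UTR length change and expression fold change.

    Computes Spearman and Pearson correlations and the least-squares slope
    of lfc on delta-length over genes present in both inputs.  Degenerate
    (zero-variance) inputs yield NaN statistics with a flag.
    """
    genes = sorted(set(delta_weighted_len) & set(gene_lfc))
    if len(genes) < 3:
        raise ValueError("need >= 3 genes with both quantities")
    x = np.array([delta_weighted_len[g] for g in genes], dtype=float)
    y = np.array([gene_lfc[g] for g in genes], dtype=float)
    out: dict = {"n": len(genes), "degenerate": False}
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        out.update(
            degenerate=True, spearman_rho=float("nan"), spearman_p=float("nan"),
            pearson_r=float("nan"), pearson_p=float("nan"),
            slope=0.0 if np.allclose(y, y[0]) else float("nan"),
            intercept=float(np.mean(y)),
        )
        return out
    rho, rho_p = stats.spearmanr(x, y)
    r, r_p = stats.pearsonr(x, y)
    reg = stats.linregress(x, y)
    out.update(
        spearman_rho=float(rho), spearman_p=float(rho_p),
        pearson_r=float(r), pearson_p=float(r_p),
        slope=float(reg.slope), intercept=float(reg.intercept),
        slope_p=float(reg.pvalue),
    )
    return out


def shift_results_table(results: Sequence[UTRShiftResult]) -> pd.DataFrame:
    """UTR-shift results as a tidy frame (gene, len_a, len_b, p, call)."""
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "weighted_len_a": r.weighted_len_a,
                "weighted_len_b": r.weighted_len_b,
                "p_value": r.p_value,
                "call": r.call.value,
                "reason": r.reason or "",
            }
            for r in results
        ]
    )


def switch_events_table(events: Sequence[SwitchEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "cond_a": e.condition_pair[0],
                "cond_b": e.condition_pair[1],
                "max_shift_pac": e.max_shift_pac or "",
                "delta_pau": e.delta_pau,
                "total_reads_ok": e.total_reads_ok,
                "delta_ok": e.delta_ok,
                "de_pac_ok": e.de_pac_ok,
                "is_switch": e.is_switch,
            }
            for e in events
        ]
    )
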