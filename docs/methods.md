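# Methods

This note documents the models, rules and numerical choices behind
`apakit`, and what the simulation-based tests do and do not establish.

## Gene models and genic regions

Genes are collapsed to a single model per locus: the union of exons over
all isoforms and the most distal stop codon along the transcription
direction. This matches the gene-level resolution of the downstream
analysis (PACs are assigned to genes, not isoforms). Internal coordinates
are 0-based half-open (BED convention); GFF3 is converted on read.

Annotated 3'UTRs are extended 120 nt downstream of their annotated end,
because authentic cleavage sites commonly fall past annotated transcript
ends. A protein-coding gene without an annotated 3'UTR receives a 338-nt
3'UTR downstream of its stop codon — the Arabidopsis genome-average 3'UTR
length (218 nt) plus the 120-nt extension. Both values are configurable
(`utr_extension`, `default_utr`).

Positions are classified with priority UTR3 > UTR3_EXTENDED > CDS >
INTRON > UTR5 within and across overlapping same-strand genes; antisense
overlap is resolved purely by strand match. The priority order is a design
choice (cleavage sites are overwhelmingly 3'UTR events, so UTR labels win
when annotations overlap); remaining ties break deterministically on gene
id. Extension is clipped to chromosome bounds only when a chrom-sizes
table is supplied.

## PAC calling

Cleavage sites within 24 nt are grouped by single-linkage chaining:
per (chromosome, strand), positions pooled over **all** samples are
sorted, and adjacent positions with gap ≤ 24 nt (boundary inclusive) join
the same cluster. Chaining means a cluster's end-to-end span can exceed
24 nt. Pooling before clustering (rather than clustering per sample and
merging) keeps PAC boundaries identical across samples; it is the simplest
reading of a fixed-window grouping rule and is verified against a
brute-force transitive-closure oracle.

The representative site is the member with the highest pooled count; ties
break toward the 3' (downstream) end, where cleavage heterogeneity tends
to trail. PACs with fewer than 10 tags summed over all samples are
discarded (a total of exactly 10 is kept). Gene assignment classifies only
the representative site, so a PAC spanning an annotation boundary is
assigned to a single gene, never double-counted.

## PAU and distribution comparison

PAU of a PAC in a sample is its count over the gene total in that sample;
it is undefined (NaN) where the gene total is zero. Condition-level PAU is
the arithmetic mean of per-replicate PAU over replicates where the gene is
expressed; a pooled count-ratio variant is available
(`condition_method="pooled"`). The mean-of-replicates default weights
replicates equally regardless of depth.

Condition distributions are compared by the two-sample K–S test on pooled
per-PAC condition PAU values. PACs with zero usage in a condition
(expressed elsewhere only) are excluded from pooling so all values lie in
(0, 1]. Plots use log2 PAU; since the K–S D statistic is invariant under
any strictly monotone transform, the log base affects only the plot, and
the implementation asserts this invariance at run time. Pooling can be
restricted to genic-region subsets (`region_of`/`regions`) since either
pooling scope is defensible. The mountain plot is the folded ECDF
min(F, 1−F) with a right-continuous F = i/n; the asymptotic K–S p-value
treats pooled PACs as independent, which PACs of one gene are not — D is
reported as a descriptive distance, and the p-value should be read with
that caveat.

## Differential testing

The NB test is intentionally self-contained and desk-scale:

- **Size factors**: median-of-ratios — per-feature geometric means over
  samples (features containing any zero excluded), per-sample median of
  count/geomean. If no feature is nonzero everywhere, library-size factors
  normalized to geometric mean 1 are used with a warning. Factors are
  computed per compared pair.
- **Dispersion**: per-feature method of moments on the within-group
  variance pooled across the two groups, clipped at zero, then **floored
  at the ensemble median dispersion** and finally at 1e-8. The floor is
  the package's moderation step: with 3 replicates per group the raw
  moment estimator is noisy enough that a normal-reference Wald test is
  anticonservative (empirically ≈ 12% of null features at p < 0.05), while
  a t(4) reference is calibrated but its heavy tails make BH-adjusted
  discoveries at n = 3 essentially unreachable. Flooring at the ensemble
  median removes the downward-noise half of the estimator without fitting
  a mean–dispersion trend; under the reference null simulation the
  rejection fraction is ≈ 0.05 and power is retained. No trend fitting or
  empirical-Bayes shrinkage is attempted.
- **Wald test**: log2 fold change of group means with pseudo-mean 0.5 for
  stability at low counts; delta-method standard error from the NB
  variance function var = μ + αμ²; two-sided normal p-values. All-zero
  features get p = 1, lfc = 0.
- **Multiplicity**: Benjamini–Hochberg step-up with enforced monotonicity;
  NaN p-values propagate and are excluded from m. Calls use strict
  padj < α (α = 0.05), so padj exactly at α is not called.

A "DE-PAC APA gene" is a gene with ≥ 2 PACs of which ≥ 1 is a DE-PAC;
single-PAC genes are never APA genes.

## Switch calling and 3'UTR length

A gene switches between two conditions when (1) its summed tag count is
strictly > 10 in **each** condition (enforcing the threshold per condition
is stricter than on the pair sum and avoids calling a gene silent in one
condition), (2) some PAC shifts usage by |ΔPAU| ≥ 0.1 (equivalently, the
max-|shift| PAC does), and (3) at least one of its PACs is a DE-PAC for
that pair. The reported shift is the signed ΔPAU of the max-shift PAC.

The weighted 3'UTR length of a gene is Σ aᵢbᵢ / Σ bᵢ with aᵢ the distance
from the stop codon (start of the extended 3'UTR) to site i and bᵢ its
replicate-pooled tag count — the k-site generalization of the two-site
formula. Only PACs in the annotated or extended 3'UTR enter; genes whose
PACs all fall elsewhere are excluded from length analyses only. Whether a
gene's 3'UTR changed significantly is tested on the proximal-vs-distal
count composition: no specific test is mandated by the p < 0.01 rule the
analysis follows, so Fisher's exact test was chosen for two sites (exact
at low counts) and the chi-square test on the k×2 table for more, falling
back to a deterministic exact conditional enumeration (multivariate
hypergeometric, probability-ordering two-sided) when any expected cell is
below 5 and the table total is ≤ 500. A significant gene is LENGTHENED if
its weighted length increased in the second condition, SHORTENED if it
decreased. The shift summary reports the shortened:lengthened count ratio
(proximal:distal preference) and median weighted-length changes per class.

The length–expression analysis correlates per-gene Δ weighted length with
the gene-level log2 fold change (Spearman, Pearson, least-squares slope);
degenerate inputs are flagged rather than reported as zeros.

## Synthetic data

The simulator emulates the statistical structure the analysis assumes, at
desk scale. Defaults define the reference conditions: 200 genes on 2
chromosomes, two conditions × 3 replicates, gene depth NB(mean 100,
dispersion 0.05), 1–3 true sites per gene with probabilities
(0.40, 0.35, 0.25), 20% of multi-site genes switching by ΔPAU 0.3, 10% of
genes differentially expressed at |lfc| = 2, cleavage jitter Gaussian with
sd 3 nt (rounded, clipped to the gene territory), and 10% of genes without
an annotated 3'UTR to exercise the 338-nt default. Per replicate, the gene
total is drawn NB and split multinomially across sites by that condition's
true PAU, so counts are exactly conserved by construction. True sites are
spaced more than 24 + 6·jitter_sd nt apart so each maps to one recoverable
cluster; switching genes keep their moving pair near 50:50 baseline usage
so the ±0.3 shift stays inside [0, 1] with headroom. One global seed
drives per-purpose substreams; outputs are byte-identical across runs.

What the simulator does **not** emulate: internal-priming artifacts,
sequence content (no FASTA/FASTQ), isoform-level structure, mapping
errors, overlapping genes, or biologically calibrated multi-condition
time series. Passing recovery tests therefore demonstrates correctness of
the statistical machinery under the stated model, not robustness to those
real-data complications.

## Evaluation sizes and numerical choices

The end-to-end recovery check runs the reference design and scores: PAC
recovery (fraction of true sites with a same-gene PAC representative
within ±10 nt), PAU RMSE on genes with condition totals ≥ 50, and switch
sensitivity/FDR. Because the reference design contains only ~24 true
switch genes, a single run's FDR moves in steps of ~0.04; the test
therefore pools hit/call counts over three fixed seeds (~70 true switch
genes), a plainly better small-sample estimator of the same rates. The
null-calibration experiment uses 2,000 features at 3-vs-3; the
null-correlation experiment 500 genes. These sizes keep the whole suite
fast while leaving the binomial noise on each rate well inside the margins
being asserted.

Other numerical details: BH uses a stable mergesort ordering; the exact
k×2 enumeration compares log-probabilities with a 1e-9 relative tie
tolerance; rep-site ties and catalog classification ties break
deterministically; summary percentages are rounded as conventionally
reported (integers for ratios, two decimals for mapping rates, with the
rate denominator being the reads that entered alignment).

## Known limitations

- Gene-level (not isoform-level) assignment; antisense and overlapping
  gene resolution is by strand and priority order only.
- No internal-priming (A-rich) filtering; inputs are assumed pre-filtered.
- The NB test omits trend-fitted dispersion shrinkage and outlier
  handling; at deeper replication its moderation floor is increasingly
  conservative relative to trend-based methods.
- K–S p-values on pooled PACs ignore within-gene dependence.
- The exact k×2 fallback is exponential in principle; above 500 total
  counts the chi-square approximation is used regardless of expected-cell
  size (expected counts are rarely small there).
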