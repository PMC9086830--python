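"""Weighted 3'UTR length and lengthen/shorten calls between conditions.

The weighted length of a gene's 3'UTR is the tag-count-weighted mean
distance from the stop codon to each poly(A) site: (a1*b1 + a2*b2)/(b1 + b2)
for two sites.  A gene is called lengthened/shortened when its
proximal-vs-distal count composition differs between conditions at p < 0.01.
"""

from apakit.apa_analysis import shift_summary, utr_shift_test, weighted_utr_length

# two poly(A) sites 100 and 200 nt past the stop codon
print("weighted length, counts (3,1):", weighted_utr_length([100, 200], [3, 1]))
# -> 125.0 nt: usage is dominated by the proximal site

# condition A uses the proximal site (90:10), condition B splits 50:50
res = utr_shift_test("geneX", [100, 200], [90, 10], [50, 50])
print(
    f"{res.gene_id}: {res.weighted_len_a:.0f} nt -> {res.weighted_len_b:.0f} nt, "
    f"p = {res.p_value:.2e}, call = {res.call.value}"
)

# an unchanged gene for contrast
ns = utr_shift_test("geneY", [120, 260], [40, 60], [38, 62])
print(f"{ns.gene_id}: p = {ns.p_value:.2f}, call = {ns.call.value}")

summary = shift_summary([res, ns])
print(summary)
# n_lengthened counts genes preferring distal sites in B; the
# proximal_to_distal_ratio is the shortened:lengthened gene ratio.
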