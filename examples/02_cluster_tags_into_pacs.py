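"""Cluster single-nucleotide cleavage sites into poly(A) clusters (PACs).

Builds a tiny hand-made tag set and shows the 24-nt single-linkage rule:
sites within 24 nt chain into one cluster (so a chain can span more than
24 nt end to end), and the representative site is the highest-count member.
"""

from apakit.pac import TagSet, cluster_sites, filter_pacs

tags = TagSet(sample_id="rep1")
for pos, n in [(1000, 12), (1010, 5), (1030, 3), (1100, 9), (1101, 2)]:
    tags.add("chr1", "+", pos, n)

pacs = cluster_sites([tags], window_nt=24)
for p in pacs:
    print(
        f"{p.pac_id}: span {p.start}-{p.end}, rep_site {p.rep_site}, "
        f"{p.total} tags"
    )
# Sites 1000/1010/1030 chain (gaps 10 and 20 <= 24) into one 31-nt cluster
# represented by position 1000 (12 tags); 1100/1101 form a second cluster.

kept = filter_pacs(pacs, min_total=10)
print(f"{len(kept)} of {len(pacs)} PACs have >= 10 tags over all samples")
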