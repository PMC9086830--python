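"""Tag loading, 24-nt cluster calling, filtering, and gene assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apakit.pac import (
    PAC,
    TagSet,
    assign_pacs_to_genes,
    cluster_sites,
    filter_pacs,
    load_tags,
    region_summary,
)
from apakit.annotation import GenicRegion


def _tagset(sample_id, sites):
    ts = TagSet(sample_id=sample_id)
    for (chrom, strand, pos), c in sites.items():
        ts.add(chrom, strand, pos, c)
    return ts


class TestLoadTags:
    def test_bed_duplicates_aggregate(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t99\t100\tt\t0\t+\nchr1\t99\t100\tt\t0\t+\n")
        ts = load_tags(bed, "s1")
        assert ts.counts == {("chr1", "+", 99): 2}

    def test_minus_strand_cleavage_is_five_prime_base(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t100\t150\tt\t0\t-\n")
        ts = load_tags(bed, "s1")
        assert ts.counts == {("chr1", "-", 100): 1}

    def test_plus_strand_cleavage_is_three_prime_base(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t100\t150\tt\t0\t+\n")
        ts = load_tags(bed, "s1")
        assert ts.counts == {("chr1", "+", 149): 1}

    def test_tsv_counts_copied_verbatim(self, tmp_path):
        tsv = tmp_path / "a.tsv"
        tsv.write_text("chr1\t500\t+\t7\nchr2\t10\t-\t3\n")
        ts = load_tags(tsv, "s1", fmt="TSV")
        assert ts.counts == {("chr1", "+", 500): 7, ("chr2", "-", 10): 3}

    def test_malformed_records_skipped(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\tnotanint\t100\tt\t0\t+\nchr1\t99\t100\tt\t0\t+\n")
        ts = load_tags(bed, "s1")
        assert ts.total == 1

    def test_empty_file_is_error(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("")
        with pytest.raises(ValueError):
            load_tags(bed, "s1")


class TestClusterSites:
    def test_two_clusters_across_a_wide_gap(self):
        # 100 (5 tags) and 110 (3) chain; 140 is 30 nt away -> separate PAC
        ts = _tagset("s1", {("chr1", "+", 100): 5, ("chr1", "+", 110): 3,
                            ("chr1", "+", 140): 2})
        pacs = cluster_sites([ts])
        assert len(pacs) == 2
        first, second = pacs
        assert (first.start, first.end, first.rep_site, first.total) == (100, 111, 100, 8)
        assert (second.start, second.end, second.total) == (140, 141, 2)

    def test_chaining_can_exceed_the_window_end_to_end(self):
        ts = _tagset("s1", {("chr1", "+", 100): 1, ("chr1", "+", 120): 1,
                            ("chr1", "+", 140): 1})
        pacs = cluster_sites([ts], window_nt=24)
        assert len(pacs) == 1
        assert (pacs[0].start, pacs[0].end) == (100, 141)

    def test_single_site_spans_one_nucleotide(self):
        pacs = cluster_sites([_tagset("s1", {("chr1", "-", 55): 4})])
        assert (pacs[0].start, pacs[0].end, pacs[0].rep_site) == (55, 56, 55)

    @pytest.mark.parametrize("strand,expected_rep", [("+", 110), ("-", 100)])
    def test_rep_site_tie_breaks_downstream(self, strand, expected_rep):
        ts = _tagset("s1", {("chr1", strand, 100): 5, ("chr1", strand, 110): 5})
        pacs = cluster_sites([ts])
        assert pacs[0].rep_site == expected_rep

    def test_boundary_gap_equal_to_window_joins(self):
        ts = _tagset("s1", {("chr1", "+", 100): 1, ("chr1", "+", 124): 1})
        assert len(cluster_sites([ts], window_nt=24)) == 1
        assert len(cluster_sites([ts], window_nt=23)) == 2

    def test_sample_order_invariance(self):
        a = _tagset("a", {("chr1", "+", 10): 2, ("chr1", "+", 40): 1})
        b = _tagset("b", {("chr1", "+", 12): 3, ("chr2", "-", 7): 4})
        p1 = cluster_sites([a, b])
        p2 = cluster_sites([b, a])
        key = lambda p: (p.chrom, p.strand, p.start, p.end, p.rep_site,
                         tuple(sorted(p.counts_by_sample.items())))
        assert [key(p) for p in p1] == [key(p) for p in p2]

    def test_count_conservation_per_sample(self):
        rng = np.random.default_rng(5)
        tagsets = []
        for s in ("s1", "s2"):
            ts = TagSet(sample_id=s)
            for pos in rng.integers(0, 2000, size=200):
                ts.add("chr1", "+", int(pos))
            tagsets.append(ts)
        pacs = cluster_sites(tagsets)
        for ts in tagsets:
            assert sum(p.count(ts.sample_id) for p in pacs) == ts.total

    def test_negative_window_is_error(self):
        with pytest.raises(ValueError):
            cluster_sites([_tagset("s", {("chr1", "+", 1): 1})], window_nt=-1)

    @given(
        positions=st.lists(st.integers(0, 10_000), min_size=1, max_size=50),
        window=st.integers(0, 40),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_transitive_closure(self, positions, window):
        """Single-linkage chaining equals the transitive closure of |p-q|<=w."""
        ts = TagSet(sample_id="s")
        for p in positions:
            ts.add("chr1", "+", p)
        got_members = sorted(
            tuple(sorted({q for q in set(positions) if p.start <= q < p.end}))
            for p in cluster_sites([ts], window_nt=window)
        )
        assert got_members == sorted(map(tuple, _oracle_clusters(set(positions), window)))

    def test_oracle_equivalence_bulk_random(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            pos = set(rng.integers(0, 10_000, size=rng.integers(1, 51)).tolist())
            w = int(rng.integers(0, 40))
            ts = TagSet(sample_id="s")
            for p in pos:
                ts.add("chr1", "+", int(p))
            got = sorted(
                tuple(sorted(q for q in pos if p.start <= q < p.end))
                for p in cluster_sites([ts], window_nt=w)
            )
            assert got == sorted(map(tuple, _oracle_clusters(pos, w)))


def _oracle_clusters(positions, window):
    """Brute-force clustering: transitive closure of |p-q| <= window."""
    pos = sorted(positions)
    parent = {p: p for p in pos}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for p in pos:
        for q in pos:
            if p < q and q - p <= window:
                parent[find(q)] = find(p)
    groups = {}
    for p in pos:
        groups.setdefault(find(p), []).append(p)
    return [sorted(g) for g in groups.values()]


class TestFilterAndAssign:
    def _pac(self, counts, **kw):
        defaults = dict(pac_id="p", chrom="chr1", strand="+", start=0, end=1,
                        rep_site=0)
        defaults.update(kw)
        return PAC(counts_by_sample=counts, **defaults)

    def test_total_nine_removed_ten_kept(self):
        low = self._pac({"a": 3, "b": 3, "c": 3})
        edge = self._pac({"a": 4, "b": 3, "c": 3})
        assert filter_pacs([low, edge], min_total=10) == [edge]

    def test_min_total_zero_is_identity(self):
        pacs = [self._pac({"a": 1}), self._pac({"a": 0})]
        assert filter_pacs(pacs, min_total=0) == pacs

    def test_assignment_uses_rep_site(self, toy_catalog_extended):
        # PAC spans into the intergenic gap but its rep_site is in geneA's UTR
        p = self._pac({"a": 5}, start=990, end=1200, rep_site=999)
        [got] = assign_pacs_to_genes([p], toy_catalog_extended)
        assert got.gene_id == "geneA"
        assert got.region is GenicRegion.UTR3

    def test_intergenic_rep_site_stays_unassigned(self, toy_catalog_extended):
        p = self._pac({"a": 5}, start=2000, end=2001, rep_site=2000)
        [got] = assign_pacs_to_genes([p], toy_catalog_extended)
        assert got.gene_id is None
        assert got.region is GenicRegion.INTERGENIC

    def test_region_summary_tallies_pacs_and_pats(self, toy_catalog_extended):
        pacs = assign_pacs_to_genes(
            [
                self._pac({"a": 5}, rep_site=800, start=800, end=801),
                self._pac({"a": 3}, rep_site=1050, start=1050, end=1051),
                self._pac({"a": 2}, rep_site=2000, start=2000, end=2001),
            ],
            toy_catalog_extended,
        )
        df = region_summary(pacs)
        assert df.loc["UTR3", "n_pacs"] == 1
        assert df.loc["UTR3", "n_pats"] == 5
        assert df["n_pats"].sum() == 10
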