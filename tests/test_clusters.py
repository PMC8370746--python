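"""Cluster calling, enrichment statistics, replicate merging and annotation."""

import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucago.clusters import (
    AnnotationIndex,
    Cluster,
    annotate_cluster,
    call_candidate_clusters,
    enrichment_test,
    filter_significant,
    fisher_exact_two_sided,
    rank_and_partition,
    reproducible_merge,
)
from nucago.intervals import GenomicInterval


def fisher_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration with exact integer binomials."""
    n1, n2, k = a + b, c + d, a + c
    denom = comb(n1 + n2, k)

    def pmf(x):
        return comb(n1, x) * comb(n2, k - x) / denom

    p_obs = pmf(a)
    total = 0.0
    for x in range(max(0, k - n2), min(n1, k) + 1):
        px = pmf(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


class TestEnrichmentTest:
    def test_fisher_matches_enumeration_oracle_small_margins(self):
        for n1 in range(0, 13):
            for n2 in range(0, 13):
                for a in range(n1 + 1):
                    for c in range(n2 + 1):
                        got = fisher_exact_two_sided(a, n1 - a, c, n2 - c)
                        want = fisher_oracle(a, n1 - a, c, n2 - c)
                        assert got == pytest.approx(want, abs=1e-10), (a, n1, c, n2)

    def test_known_table_three_one_one_three(self):
        # all tables with both margins (4, 4): p = 34/70
        assert fisher_exact_two_sided(3, 1, 1, 3) == pytest.approx(34 / 70, abs=1e-12)

    def test_eightfold_change_is_log2_three_without_pseudocount(self):
        _p, fc = enrichment_test(40, 1_000_000, 5, 1_000_000, pseudocount=0)
        assert fc == pytest.approx(3.0, abs=1e-12)

    def test_balanced_table_is_null(self):
        p, fc = enrichment_test(5, 10, 5, 10, pseudocount=0)
        assert p == pytest.approx(1.0)
        assert fc == pytest.approx(0.0)

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            enrichment_test(0, 0, 5, 100)

    def test_yates_branch_close_to_fisher_at_large_expected(self):
        args = (4000, 996_000, 2000, 998_000)
        p_auto, _ = enrichment_test(*args, method="auto")
        p_fisher, _ = enrichment_test(*args, method="fisher")
        assert p_auto == pytest.approx(p_fisher, rel=0.02)

    @settings(max_examples=60, deadline=None)
    @given(
        ip=st.integers(0, 40),
        bg=st.integers(0, 40),
        ip_total=st.integers(100, 2000),
        bg_total=st.integers(100, 2000),
    )
    def test_monotone_in_ip_count(self, ip, bg, ip_total, bg_total):
        """More IP reads never decrease the fold change.

        The two-sided exact p is not strictly monotone when the observed
        count shifts the table margins (a structural property of
        minimum-likelihood two-sided tests), so only the fold change is
        asserted here; p monotonicity is checked on the large-sample branch
        below.
        """
        _p1, fc1 = enrichment_test(ip, ip_total, bg, bg_total, method="fisher")
        _p2, fc2 = enrichment_test(ip + 1, ip_total, bg, bg_total, method="fisher")
        assert fc2 >= fc1

    def test_p_monotone_on_large_sample_branch(self):
        base = None
        for ip in range(4000, 4500, 100):
            p, _fc = enrichment_test(ip, 1_000_000, 2000, 1_000_000, method="yates")
            if base is not None:
                assert p <= base
            base = p


class TestFilterSignificant:
    @pytest.mark.parametrize(
        "p,fc,kept",
        [
            (0.049, 2.0, True),  # both thresholds met at the boundary
            (0.05, 5.0, False),  # p threshold is strict
            (0.001, 1.99, False),  # fold-change threshold is >= 2
            (0.0499999, 1.9999, False),
        ],
    )
    def test_boundary_behaviour(self, p, fc, kept):
        cl = Cluster(GenomicInterval("chrT", 0, 100, "+"), p_value=p, log2fc=fc)
        assert (len(filter_significant([cl])) == 1) is kept


def merge_oracle(rep1, rep2, threshold=1 / 3):
    """Brute-force connected components over the bipartite 1/3-overlap graph."""
    nodes = [("a", iv) for iv in rep1] + [("b", iv) for iv in rep2]
    n = len(nodes)
    adj = {i: set() for i in range(n)}
    for i in range(len(rep1)):
        for j in range(len(rep2)):
            a, b = rep1[i], rep2[j]
            if a.strand != b.strand or a.chrom != b.chrom:
                continue
            inter = max(0, min(a.end, b.end) - max(a.start, b.start))
            union = a.length + b.length - inter
            if inter > 0 and inter / union >= threshold:
                adj[i].add(len(rep1) + j)
                adj[len(rep1) + j].add(i)
    seen, out = set(), []
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            x = stack.pop()
            comp.append(x)
            for y in adj[x] - seen:
                seen.add(y)
                stack.append(y)
        sides = {nodes[i][0] for i in comp}
        if sides == {"a", "b"}:
            ivs = [nodes[i][1] for i in comp]
            out.append(
                GenomicInterval(
                    ivs[0].chrom,
                    min(v.start for v in ivs),
                    max(v.end for v in ivs),
                    ivs[0].strand,
                )
            )
    return sorted(out)


class TestReproducibleMerge:
    def test_worked_example_union(self):
        r1 = [GenomicInterval("chrT", 100, 200, "+")]
        r2 = [GenomicInterval("chrT", 150, 250, "+")]
        assert reproducible_merge(r1, r2) == [GenomicInterval("chrT", 100, 250, "+")]

    def test_unmatched_cluster_discarded(self):
        r1 = [GenomicInterval("chrT", 100, 200, "+")]
        assert reproducible_merge(r1, []) == []
        assert reproducible_merge(r1, [GenomicInterval("chrT", 500, 600, "+")]) == []

    def test_opposite_strands_never_merge(self):
        r1 = [GenomicInterval("chrT", 100, 200, "+")]
        r2 = [GenomicInterval("chrT", 100, 200, "-")]
        assert reproducible_merge(r1, r2) == []

    def test_transitive_chain_forms_one_cluster(self):
        r1 = [
            GenomicInterval("chrT", 100, 200, "+"),
            GenomicInterval("chrT", 180, 300, "+"),
        ]
        r2 = [GenomicInterval("chrT", 140, 260, "+")]
        merged = reproducible_merge(r1, r2)
        assert merged == [GenomicInterval("chrT", 100, 300, "+")]

    @settings(max_examples=80, deadline=None)
    @given(
        raw1=st.lists(
            st.tuples(st.integers(0, 500), st.integers(10, 120), st.sampled_from("+-")),
            max_size=8,
        ),
        raw2=st.lists(
            st.tuples(st.integers(0, 500), st.integers(10, 120), st.sampled_from("+-")),
            max_size=8,
        ),
    )
    def test_matches_brute_force_and_is_symmetric(self, raw1, raw2):
        r1 = [GenomicInterval("chrT", s, s + w, t) for s, w, t in raw1]
        r2 = [GenomicInterval("chrT", s, s + w, t) for s, w, t in raw2]
        got = reproducible_merge(r1, r2)
        assert got == merge_oracle(r1, r2)
        assert got == reproducible_merge(r2, r1)


class TestAnnotate:
    def test_priority_cds_over_intron(self, pc_gene_annotation):
        index = AnnotationIndex(pc_gene_annotation)
        # spans the first exon/intron boundary: CDS exon wins over intron
        cat, is_mirna, gene = annotate_cluster(
            GenomicInterval("chrT", 250, 350, "+"), index
        )
        assert cat == "CDS_exon" and not is_mirna and gene == "PC1"

    def test_intron_only(self, pc_gene_annotation):
        index = AnnotationIndex(pc_gene_annotation)
        cat, _m, _g = annotate_cluster(GenomicInterval("chrT", 350, 450, "+"), index)
        assert cat == "pc_intron"

    def test_no_overlap_is_intergenic(self, pc_gene_annotation):
        index = AnnotationIndex(pc_gene_annotation)
        cat, is_mirna, gene = annotate_cluster(
            GenomicInterval("chrT", 5000, 5100, "+"), index
        )
        assert cat == "intergenic" and gene == ""

    def test_mirna_locus_sets_flag(self, pc_gene_annotation):
        index = AnnotationIndex(pc_gene_annotation)
        cat, is_mirna, gene = annotate_cluster(
            GenomicInterval("chrT", 2010, 2060, "-"), index
        )
        assert cat == "nc_exon" and is_mirna and gene == "MIR1"

    def test_strand_mismatch_ignores_feature(self, pc_gene_annotation):
        index = AnnotationIndex(pc_gene_annotation)
        cat, _m, _g = annotate_cluster(GenomicInterval("chrT", 2010, 2060, "+"), index)
        assert cat == "intergenic"

    def test_utr_priorities(self, pc_gene_annotation):
        index = AnnotationIndex(pc_gene_annotation)
        cat, _m, _g = annotate_cluster(GenomicInterval("chrT", 110, 150, "+"), index)
        assert cat == "UTR5"
        cat, _m, _g = annotate_cluster(GenomicInterval("chrT", 1010, 1050, "+"), index)
        assert cat == "UTR3"


class TestRanking:
    def _clusters(self):
        out = []
        for i in range(6):
            out.append(
                Cluster(
                    GenomicInterval("chrT", 100 * i, 100 * i + 50, "+"),
                    p_value=0.01,
                    log2fc=2.0 + (i % 3),
                    is_mirna=(i % 2 == 0),
                    category="nc_exon" if i % 2 == 0 else "pc_intron",
                )
            )
        return out

    def test_tie_break_is_deterministic(self):
        clusters = self._clusters()
        r1 = rank_and_partition(clusters, 4)
        r2 = rank_and_partition(list(reversed(clusters)), 4)
        assert [c.interval for c in r1["top"]] == [c.interval for c in r2["top"]]
        # ties on p broken by descending log2fc
        fcs = [c.log2fc for c in r1["top"]]
        assert fcs == sorted(fcs, reverse=True)

    def test_top_zero_is_empty(self):
        r = rank_and_partition(self._clusters(), 0)
        assert r["top"] == [] and r["top_non_mirna"] == []
        assert r["category_counts"] == {}

    def test_non_mirna_partition_excludes_mirna(self):
        r = rank_and_partition(self._clusters(), 6)
        assert all(not c.is_mirna for c in r["top_non_mirna"])
        assert r["n_mirna_in_top"] == 3


class TestCandidateCalling:
    def test_empty_input(self):
        assert call_candidate_clusters([], 1000) == []

    def test_constant_depth_yields_no_candidates(self):
        # perfectly tiled reads: depth is exactly the mean everywhere, which
        # can never exceed a threshold with per-position p < 0.001
        reads = [
            GenomicInterval("chrT", s, s + 50, "+") for s in range(0, 10_000, 50)
        ] * 5
        assert call_candidate_clusters(reads, 10_000) == []

    def test_single_hot_region_is_one_candidate(self):
        rng = np.random.default_rng(0)
        reads = [
            GenomicInterval("chrT", int(s), int(s) + 50, "+")
            for s in rng.integers(0, 19_950, size=2000)
        ]
        # 10x density inside [5000, 5100)
        reads += [
            GenomicInterval("chrT", int(s), int(s) + 50, "+")
            for s in rng.integers(4951, 5100, size=int(9 * 2000 * 149 / 19_950))
        ]
        cands = call_candidate_clusters(reads, 20_000)
        assert len(cands) == 1
        region = GenomicInterval("chrT", 5000, 5100, "+")
        covered = cands[0].intersection_length(region)
        assert covered >= 0.8 * region.length
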