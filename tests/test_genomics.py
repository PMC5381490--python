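import numpy as np
import pytest
from hypothesis import given, strategies as st

from tsmirnet.genomics import (
    MiRNALocus,
    PromoterRegion,
    call_mirna_clusters,
    assign_tss,
    compute_binding_profile,
    define_promoter,
    normalize_mirna_name,
    promoters_for_loci,
    scan_promoters,
)
from tsmirnet.io_formats import TFBSRecord


def locus(name, start, end, strand="+", chrom="chr1"):
    return MiRNALocus(name, name, chrom, start, end, strand)


class TestNameNormalization:
    def test_precursor_copy_suffix_stripped_against_known_matures(self):
        assert normalize_mirna_name("mir-133a-1", known_mature={"miR-133a"}) == "miR-133a"

    def test_identity_for_clean_mature_name(self):
        assert normalize_mirna_name("miR-126") == "miR-126"

    def test_alias_map_applied_last(self):
        assert normalize_mirna_name("miR-208a", alias_map={"miR-208a": "miR-208"}) == "miR-208"
        # suffix strip resolves to an alias key, then the alias fires
        assert (
            normalize_mirna_name("mir-513a-2", alias_map={"miR-513a": "miR-513"}) == "miR-513"
        )

    def test_unknown_names_pass_through_prefix_normalized(self):
        assert normalize_mirna_name("hsa-mir-9999") == "miR-9999"

    def test_suffix_kept_when_stem_unknown(self):
        # "-2" could be a genuine family member; only strip when the stem is known
        assert normalize_mirna_name("miR-777-2") == "miR-777-2"


class TestClusterCalling:
    def test_gap_at_most_10kb_joins(self):
        loci = [locus("a", 1000, 1100), locus("b", 11099, 11200)]  # gap 9,999
        (cluster,) = call_mirna_clusters(loci)
        assert len(cluster.members) == 2

    def test_gap_above_10kb_splits(self):
        loci = [locus("a", 1000, 1100), locus("b", 11101, 11200)]  # gap 10,001
        assert call_mirna_clusters(loci) == []

    def test_boundary_gap_exactly_10kb_joins(self):
        loci = [locus("a", 1000, 1100), locus("b", 11100, 11200)]
        assert len(call_mirna_clusters(loci)) == 1

    def test_opposite_strands_never_cluster(self):
        loci = [locus("a", 1000, 1100, "+"), locus("b", 1000, 1100, "-")]
        assert call_mirna_clusters(loci) == []

    def test_overlapping_loci_join(self):
        loci = [locus("a", 1000, 1500), locus("b", 1200, 1300)]
        assert len(call_mirna_clusters(loci)) == 1

    def test_singletons_are_not_clusters(self):
        assert call_mirna_clusters([locus("a", 0, 100)]) == []

    @given(
        starts=st.lists(st.integers(0, 500_000), min_size=2, max_size=20, unique=True),
        shift=st.integers(0, 10**6),
        seed=st.integers(0, 10),
    )
    def test_invariant_to_order_and_translation(self, starts, shift, seed):
        loci = [locus(f"m{i}", s, s + 80) for i, s in enumerate(starts)]
        rng = np.random.default_rng(seed)
        shuffled = [loci[i] for i in rng.permutation(len(loci))]
        shifted = [locus(m.raw_name, m.start + shift, m.end + shift) for m in loci]

        def signature(clusters, offset=0):
            return sorted(
                tuple(sorted(x.raw_name for x in c.members)) for c in clusters
            )

        base = signature(call_mirna_clusters(loci))
        assert signature(call_mirna_clusters(shuffled)) == base
        assert signature(call_mirna_clusters(shifted)) == base


class TestTSSAssignment:
    def test_experimental_tss_wins(self):
        m = locus("a", 200_000, 200_080)
        assert assign_tss(m, {"a": ("chr1", 150_000)}, []) == (150_000, "experimental")

    def test_experimental_tss_on_wrong_chromosome_rejected(self):
        m = locus("a", 200_000, 200_080)
        with pytest.raises(ValueError, match="chr2"):
            assign_tss(m, {"a": ("chr2", 150_000)}, [])

    def test_clustered_locus_inherits_cluster_five_prime(self):
        a, b = locus("a", 200_000, 200_080), locus("b", 210_000, 215_000)
        (cluster,) = call_mirna_clusters([a, b])
        assert assign_tss(b, None, [cluster]) == (200_000, "cluster_start")

    def test_minus_strand_cluster_uses_right_edge(self):
        a, b = locus("a", 200_000, 200_080, "-"), locus("b", 205_000, 205_080, "-")
        (cluster,) = call_mirna_clusters([a, b])
        assert assign_tss(a, None, [cluster]) == (205_080, "cluster_start")

    def test_minus_strand_singleton_uses_its_own_five_prime(self):
        m = locus("a", 300_000, 300_080, "-")
        assert assign_tss(m, None, []) == (300_080, "locus_start")


class TestPromoter:
    def test_plus_strand_window(self):
        p = define_promoter(100_000, "+", chrom_length=1_000_000)
        assert (p.start, p.end) == (95_000, 101_000)

    def test_minus_strand_window_is_reflected(self):
        p = define_promoter(100_000, "-", chrom_length=1_000_000)
        assert (p.start, p.end) == (99_000, 105_000)

    def test_left_edge_clamp(self):
        p = define_promoter(3_000, "+", chrom_length=1_000_000)
        assert (p.start, p.end) == (0, 4_000)

    def test_right_edge_clamp(self):
        p = define_promoter(999_500, "-", chrom_length=1_000_000)
        assert (p.start, p.end) == (998_500, 1_000_000)

    def test_tss_outside_chromosome_is_domain_error(self):
        with pytest.raises(ValueError, match="outside"):
            define_promoter(-5, "+", chrom_length=100)
        with pytest.raises(ValueError, match="outside"):
            define_promoter(200, "+", chrom_length=100)

    @given(tss=st.integers(10_000, 10**6), strand=st.sampled_from("+-"))
    def test_unclamped_length_is_upstream_plus_downstream(self, tss, strand):
        p = define_promoter(tss, strand, chrom_length=2 * 10**6)
        assert p.end - p.start == 6_000


def _prom(owner, start, end, strand="+", tss=None, chrom="chr1"):
    if tss is None:
        tss = start + 5_000 if strand == "+" else start + 1_000
    return PromoterRegion(owner, chrom, start, end, strand, tss, "experimental")


class TestScan:
    def test_contained_site_makes_an_edge(self):
        edges = scan_promoters(
            [_prom("miR-1", 95_000, 101_000)], [TFBSRecord("SRF", "chr1", 95_100, 95_200)]
        )
        assert [(e.source, e.target, e.site_count) for e in edges] == [("SRF", "miR-1", 1)]

    def test_one_bp_overlap_counts(self):
        edges = scan_promoters(
            [_prom("miR-1", 95_000, 101_000)], [TFBSRecord("SRF", "chr1", 94_900, 95_001)]
        )
        assert len(edges) == 1

    def test_abutting_interval_is_no_overlap(self):
        edges = scan_promoters(
            [_prom("miR-1", 95_000, 101_000)], [TFBSRecord("SRF", "chr1", 90_000, 95_000)]
        )
        assert edges == []

    def test_duplicate_sites_collapse_to_one_edge(self):
        sites = [
            TFBSRecord("SRF", "chr1", 95_100, 95_200),
            TFBSRecord("SRF", "chr1", 96_000, 96_300),
            TFBSRecord("GATA2", "chr1", 96_000, 96_300),
        ]
        edges = scan_promoters([_prom("miR-1", 95_000, 101_000)], sites)
        assert {(e.source, e.site_count) for e in edges} == {("SRF", 2), ("GATA2", 1)}

    def test_chromosomes_are_respected(self):
        edges = scan_promoters(
            [_prom("miR-1", 95_000, 101_000, chrom="chr1")],
            [TFBSRecord("SRF", "chr2", 95_100, 95_200)],
        )
        assert edges == []

    def test_min_overlap_parameter(self):
        site = TFBSRecord("SRF", "chr1", 94_950, 95_010)  # 10-bp overlap
        prom = _prom("miR-1", 95_000, 101_000)
        assert len(scan_promoters([prom], [site], min_overlap_bp=10)) == 1
        assert scan_promoters([prom], [site], min_overlap_bp=11) == []


def brute_force_scan(promoters, tfbs, min_overlap=1):
    """All-pairs overlap oracle, vectorized but with no interval index."""
    counts = {}
    ts = np.array([r.start for r in tfbs])
    te = np.array([r.end for r in tfbs])
    chroms = np.array([r.chrom for r in tfbs])
    for prom in promoters:
        overlap = np.minimum(prom.end, te) - np.maximum(prom.start, ts)
        hits = (chroms == prom.chrom) & (overlap >= min_overlap)
        for idx in np.nonzero(hits)[0]:
            key = (tfbs[idx].tf_name, prom.owner)
            counts[key] = counts.get(key, 0) + 1
    return counts


class TestScanOracle:
    def test_scan_matches_brute_force_on_random_intervals(self):
        rng = np.random.default_rng(7)
        n = 2_000
        promoters = [
            _prom(f"m{i}", int(s), int(s) + 6_000)
            for i, s in enumerate(rng.integers(0, 5 * 10**7, size=n))
        ]
        tfbs = [
            TFBSRecord(f"TF{int(t):02d}", "chr1", int(s), int(s) + int(w))
            for t, s, w in zip(
                rng.integers(0, 40, size=n),
                rng.integers(0, 5 * 10**7, size=n),
                rng.integers(50, 400, size=n),
            )
        ]
        edges = {(e.source, e.target): e.site_count for e in scan_promoters(promoters, tfbs)}
        assert edges == brute_force_scan(promoters, tfbs)


class TestBindingProfile:
    def test_single_site_in_one_bin(self):
        prom = _prom("m", 5_000, 11_000, "+", tss=10_000)
        site = TFBSRecord("A", "chr1", 9_850, 9_950)  # rel [-150, -50) -> bin [-200, 0)
        result = compute_binding_profile([prom], {"heart": [site]})
        row = result.matrix.loc["heart"]
        assert row[-200] == 100.0
        assert row.drop(-200).eq(0).all()

    def test_site_spanning_two_bins_counts_in_both(self):
        prom = _prom("m", 5_000, 11_000, "+", tss=10_000)
        site = TFBSRecord("A", "chr1", 9_900, 10_100)  # rel [-100, 100)
        result = compute_binding_profile([prom], {"heart": [site]})
        row = result.matrix.loc["heart"]
        assert row[-200] == 100.0 and row[0] == 100.0
        assert row.sum() == 200.0  # per-bin counting can exceed 100% by design

    def test_minus_strand_offsets_run_against_genome(self):
        # TSS at 10,000 on '-': genomic [10,050, 10,150) is 50-150 bp upstream
        prom = _prom("m", 9_000, 15_000, "-", tss=10_000)
        site = TFBSRecord("A", "chr1", 10_050, 10_150)
        result = compute_binding_profile([prom], {"t": [site]})
        assert result.matrix.loc["t", -200] == 100.0

    def test_zero_tfbs_tissue_flagged(self):
        prom = _prom("m", 5_000, 11_000)
        result = compute_binding_profile([prom], {"heart": [], "lung": [TFBSRecord("A", "chr1", 5_100, 5_200)]})
        assert result.empty_tissues == ["heart"]
        assert result.matrix.loc["heart"].eq(0).all()

    def test_profile_has_thirty_bins(self):
        result = compute_binding_profile([_prom("m", 5_000, 11_000)], {"t": []})
        assert list(result.matrix.columns) == list(range(-5_000, 1_000, 200))

    def test_bin_width_must_divide_window(self):
        with pytest.raises(ValueError, match="divide"):
            compute_binding_profile([], {}, bin_bp=333)


def test_promoters_for_loci_one_promoter_per_mature_name():
    loci = [
        MiRNALocus("mir-1-1", "miR-1", "chr1", 100_000, 100_080, "+"),
        MiRNALocus("mir-1-2", "miR-1", "chr1", 900_000, 900_080, "+"),
    ]
    promoters = promoters_for_loci(loci)
    assert len(promoters) == 1 and promoters[0].owner == "miR-1"
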