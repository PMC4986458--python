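"""Site/region homoplasy classification, cluster calling and the tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from polymaps.introgression import (
    IntrogressionCluster,
    RegionCall,
    RegionClass,
    SiteClass,
    allele_depth_ratio,
    classify_region,
    classify_site,
    cluster_geometry,
    detect_clusters,
    directionality_test,
    excess_homoplasy_test,
    merge_intervals,
    source_informative_sites,
)


class TestClassifySite:
    @pytest.mark.parametrize(
        "s,v,i,o,sister,expected",
        [
            ("G", "A", "G", "A", "iinumae", SiteClass.SUPPORTIVE),
            ("A", "A", "G", "G", "iinumae", SiteClass.INTROGRESSION_LIKE),
            ("T", "A", "A", "T", "iinumae", SiteClass.OUTGROUP_HOMOPLASY),
            ("T", "A", "A", "T", "vesca", SiteClass.OUTGROUP_HOMOPLASY),
            ("A", "A", "A", "A", "iinumae", SiteClass.UNINFORMATIVE),
            ("A", "A", "G", "C", "iinumae", SiteClass.UNINFORMATIVE),  # 3 states
            ("A", "A", "A", "G", "iinumae", SiteClass.UNINFORMATIVE),  # 3:1
            ("A", "G", "G", "G", "vesca", SiteClass.UNINFORMATIVE),    # 1:3
            ("A", "A", "G", "G", "vesca", SiteClass.SUPPORTIVE),
            ("G", "A", "G", "A", "vesca", SiteClass.INTROGRESSION_LIKE),
        ],
    )
    def test_patterns(self, s, v, i, o, sister, expected):
        assert classify_site(s, v, i, o, sister) is expected

    @given(
        pattern=st.sampled_from(
            [p for p in itertools.product("01", repeat=4)]
        ),
        b0=st.sampled_from("ACGT"),
        b1=st.sampled_from("ACGT"),
        sister=st.sampled_from(["vesca", "iinumae"]),
    )
    def test_base_relabelling_invariance(self, pattern, b0, b1, sister):
        """Only the partition of the four bases matters, not which
        nucleotides realise it."""
        if b0 == b1:
            return
        bases1 = ["A" if p == "0" else "G" for p in pattern]
        bases2 = [b0 if p == "0" else b1 for p in pattern]
        assert classify_site(*bases1, sister) is classify_site(*bases2, sister)


class TestClassifyRegion:
    S, I, O = (
        SiteClass.SUPPORTIVE,
        SiteClass.INTROGRESSION_LIKE,
        SiteClass.OUTGROUP_HOMOPLASY,
    )

    def test_pure_supportive(self):
        assert classify_region({"m": [self.S] * 3}) is RegionClass.SUPPORTIVE

    def test_mixed_same_sample_is_support_homoplasy(self):
        assert (
            classify_region({"m": [self.S, self.I, self.I]})
            is RegionClass.SUPPORT_HOMOPLASY
        )

    def test_single_introgression_site(self):
        assert classify_region({"m": [self.I]}) is RegionClass.INTROGRESSION_LIKE

    def test_outgroup_only(self):
        assert classify_region({"m": [self.O, self.O]}) is RegionClass.OUTGROUP

    def test_outgroup_does_not_break_classes(self):
        assert classify_region({"m": [self.I, self.O]}) is RegionClass.INTROGRESSION_LIKE
        assert classify_region({"m": [self.S, self.O]}) is RegionClass.SUPPORTIVE

    def test_no_informative_sites(self):
        assert classify_region({"m": [SiteClass.UNINFORMATIVE]}) is None

    def test_mix_across_samples_also_demotes(self):
        got = classify_region({"m": [self.S], "p": [self.I]})
        assert got is RegionClass.SUPPORT_HOMOPLASY


def track_calls(track):
    K = {
        "I": RegionClass.INTROGRESSION_LIKE,
        "S": RegionClass.SUPPORTIVE,
        "O": RegionClass.OUTGROUP,
        "H": RegionClass.SUPPORT_HOMOPLASY,
    }
    return [
        RegionCall(k, "chr1", "B1", K[t], frozenset("m"),
                   first_site=k * 10_000, last_site=k * 10_000 + 500)
        for k, t in enumerate(track)
    ]


def brute_force_clusters(track):
    """Independent enumerator: every window starting and ending at I with
    >= 2 I's and I:(S or H) ratio >= 4; overlapping windows merged."""
    wins = []
    n = len(track)
    for i in range(n):
        if track[i] != "I":
            continue
        for j in range(i + 1, n):
            if track[j] != "I":
                continue
            w = track[i : j + 1]
            ni = w.count("I")
            ns = w.count("S") + w.count("H")
            if ni >= 2 and (ns == 0 or ni >= 4 * ns):
                wins.append((i, j))
    out = []
    for a, b in merge_intervals(wins):
        ii = [k for k in range(a, b + 1) if track[k] == "I"]
        out.append((ii[0], ii[-1], len(ii)))
    return out


def impl_clusters(track):
    return [
        (c.first_site // 10_000, (c.last_site - 500) // 10_000, c.region_count)
        for c in detect_clusters(track_calls(track))
    ]


class TestDetectClusters:
    @pytest.mark.parametrize(
        "track,expected",
        [
            ("II", [(0, 1, 2)]),
            ("ISI", []),                 # ratio 2 < 4
            ("IIIISI", [(0, 5, 5)]),     # 5 I's vs 1 S: ratio 5 >= 4
            ("IOI", [(0, 2, 2)]),        # outgroup regions are neutral
            ("IHI", []),                 # support/homoplasy counts as supportive
            ("I", []),
            ("", []),
        ],
    )
    def test_examples(self, track, expected):
        assert impl_clusters(track) == expected

    def test_matches_brute_force_on_random_tracks(self):
        rng = np.random.default_rng(17)
        alphabet = np.array(list("ISOH"))
        for _ in range(300):
            track = "".join(rng.choice(alphabet, rng.integers(1, 18)))
            assert impl_clusters(track) == brute_force_clusters(track)

    def test_clusters_never_overlap_on_a_subgenome(self):
        rng = np.random.default_rng(23)
        alphabet = np.array(list("ISO"))
        for _ in range(200):
            track = "".join(rng.choice(alphabet, rng.integers(2, 25)))
            clusters = detect_clusters(track_calls(track))
            for c1, c2 in itertools.combinations(clusters, 2):
                assert c1.last_site < c2.first_site or c2.last_site < c1.first_site


class TestExcessHomoplasy:
    def test_published_counts(self):
        ratio, p_binom, p_fisher = excess_homoplasy_test(335, 196)
        assert ratio == pytest.approx(335 / 196)
        assert round(ratio, 1) == 1.7
        assert p_binom < 1e-4

    def test_symmetric_counts(self):
        ratio, p, _ = excess_homoplasy_test(10, 10)
        assert ratio == 1.0
        assert p == pytest.approx(1.0)

    def test_one_sided_extreme(self):
        ratio, p, _ = excess_homoplasy_test(5, 0)
        assert ratio == float("inf")
        assert p == pytest.approx(2 * 0.5**5)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            excess_homoplasy_test(0, 0)


class TestDirectionality:
    def test_published_unidirectional(self):
        expected, p = directionality_test(48, 0)
        assert expected == (36, 12)
        assert p < 0.001

    def test_identical_rows(self):
        assert directionality_test(36, 12)[1] == pytest.approx(1.0)
        assert directionality_test(3, 1)[1] == pytest.approx(1.0)


def make_cluster(chrom, a, b, sub):
    return IntrogressionCluster(sub, chrom, a, b, 2, frozenset("m"))


class TestClusterGeometry:
    def test_two_identical_intervals_on_different_subgenomes(self):
        c1 = make_cluster("chr5", 100, 600, "Bi")
        c2 = make_cluster("chr5", 100, 600, "B2")
        geo = cluster_geometry([c1, c2])
        assert geo.overlap_instances == 1
        assert geo.overlap_extent == 500
        assert geo.genomic_union == 500

    def test_disjoint_union_is_sum_of_spans(self):
        c1 = make_cluster("chr1", 0, 100, "B1")
        c2 = make_cluster("chr2", 0, 250, "B1")
        geo = cluster_geometry([c1, c2])
        assert geo.genomic_union == 350
        assert geo.overlap_instances == 0

    def test_same_subgenome_overlap_not_counted(self):
        c1 = make_cluster("chr1", 0, 100, "B1")
        c2 = make_cluster("chr1", 50, 150, "B1")
        geo = cluster_geometry([c1, c2])
        assert geo.overlap_instances == 0

    def test_empty(self):
        geo = cluster_geometry([])
        assert geo.count == 0 and geo.genomic_union == 0


class TestAlleleDepthRatio:
    def test_site_filters(self):
        pos = np.array([10, 20, 30])
        v = np.array([30.0, 90.0, 40.0])
        i = np.array([10.0, 10.0, 20.0])
        out = allele_depth_ratio(pos, v, i, [])
        # combined 40 < 45 dropped; ratio 9 > 8 dropped; (40,20) kept
        assert out["n_sites"] == 1
        assert out["bin_means"][0] == pytest.approx(2.0)

    def test_zero_denominator_excluded(self):
        out = allele_depth_ratio(
            np.array([10]), np.array([50.0]), np.array([0.0]), []
        )
        assert out["n_sites"] == 0

    def test_welch_direction(self):
        rng = np.random.default_rng(8)
        pos = np.arange(4000) * 1000
        v = np.full(4000, 30.0)
        i = np.full(4000, 30.0)
        v[:200] = 60.0  # first 200 kb: vesca-skewed (in cluster)
        v += rng.normal(0, 1, 4000)
        out = allele_depth_ratio(pos, v, i, [(0, 199_000)])
        assert out["mean_in"] > out["mean_out"]
        assert out["welch_t"] > 10


class TestSourceInformativeSites:
    def test_rules(self):
        rows = [
            ("T", "T", "C", "C"),  # with vesca only
            ("T", "C", "T", "C"),  # with Av only
            ("T", "T", "T", "C"),  # shared by both: neither
            ("C", "T", "T", "C"),  # not derived
        ]
        assert source_informative_sites(rows) == (1, 1)
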