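"""The core screen: window scanning, merging, phosphosites, density, charge."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from esmscreen import (
    ProteinRecord,
    ScreenConfig,
    TopologyAnnotation,
    attach_phosphosites,
    kr_density,
    merge_windows,
    net_tail_charge,
    scan_windows,
    screen_protein,
    screen_proteome,
)
from _helpers import make_tail, naive_clusters, naive_scan

CFG = ScreenConfig()


class TestScanWindows:
    def test_no_basics_no_windows(self):
        assert scan_windows(make_tail("A" * 30), CFG) == []

    def test_single_window_with_exactly_nine_basics(self):
        assert scan_windows(make_tail("KRKRKRKRK" + "A" * 21), CFG) == [1]

    def test_all_windows_containing_the_cluster_qualify(self):
        # basics at 6-14; a 30-mer holds all nine iff it starts at 1..6
        tail = make_tail("A" * 5 + "KRKRKRKRK" + "A" * 26)  # length 40
        assert scan_windows(tail, CFG) == list(range(1, 7))
        assert scan_windows(tail, CFG) == naive_scan(tail, CFG)

    def test_eight_basics_never_qualify(self):
        rng = random.Random(0)
        for _ in range(20):
            positions = rng.sample(range(60), 8)
            seq = "".join("K" if i in positions else "A" for i in range(60))
            tail = make_tail(seq)
            assert naive_scan(tail, CFG) == []
            assert scan_windows(tail, CFG) == []

    def test_short_tail_excluded_not_an_error(self):
        assert scan_windows(make_tail("K" * 29), CFG) == []

    def test_search_depth_limits_scanning_to_terminus(self):
        # cluster beyond the first 100 residues of an N-tail is invisible
        seq = "A" * 110 + "K" * 30 + "A" * 10
        assert scan_windows(make_tail(seq, terminus="N"), CFG) == []
        # ... but the same cluster near a C-terminus suffix is seen
        c_tail = make_tail("A" * 110 + "K" * 30 + "A" * 10, terminus="C", start=500)
        assert scan_windows(c_tail, CFG) != []

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        seq=st.text(alphabet="KRASTYLX", min_size=10, max_size=200),
        terminus=st.sampled_from(["N", "C"]),
    )
    def test_matches_naive_enumeration(self, seq, terminus):
        tail = make_tail(seq, terminus=terminus)
        assert scan_windows(tail, CFG) == naive_scan(tail, CFG)

    def test_lowering_min_basic_never_removes_windows(self):
        rng = random.Random(1)
        seq = "".join(rng.choice("KRAAA") for _ in range(150))
        tail = make_tail(seq)
        strict = set(scan_windows(tail, ScreenConfig(min_basic=9)))
        lax = set(scan_windows(tail, ScreenConfig(min_basic=8)))
        assert strict <= lax


class TestMergeWindows:
    def test_empty_input(self):
        assert merge_windows([], make_tail("A" * 30), CFG) == []

    def test_single_cluster_union_and_basic_span(self):
        tail = make_tail("A" * 5 + "KRKRKRKRK" + "A" * 26)
        starts = scan_windows(tail, CFG)
        (cluster,) = merge_windows(starts, tail, CFG)
        # union of windows 1-30 .. 6-35
        assert (cluster.window_union_start, cluster.window_union_end) == (1, 35)
        assert (cluster.basic_span_start, cluster.basic_span_end) == (6, 14)
        assert cluster.n_basic == 9

    def test_two_separated_clusters(self):
        seq = ["A"] * 100
        for pos in range(6, 15):
            seq[pos - 1] = "K"
        for pos in range(70, 79):
            seq[pos - 1] = "R"
        tail = make_tail("".join(seq))
        clusters = merge_windows(scan_windows(tail, CFG), tail, CFG)
        assert len(clusters) == 2
        spans = [(c.basic_span_start, c.basic_span_end) for c in clusters]
        assert spans == [(6, 14), (70, 78)]

    def test_protein_coordinates_offset_by_tail_start(self):
        tail = make_tail("KRKRKRKRK" + "A" * 21, terminus="C", start=901)
        (cluster,) = merge_windows(scan_windows(tail, CFG), tail, CFG)
        assert (cluster.basic_span_start, cluster.basic_span_end) == (901, 909)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(seq=st.text(alphabet="KRAST", min_size=30, max_size=200))
    def test_matches_from_scratch_cluster_oracle(self, seq):
        tail = make_tail(seq)
        clusters = merge_windows(scan_windows(tail, CFG), tail, CFG)
        got = [
            (c.window_union_start, c.window_union_end, c.basic_span_start,
             c.basic_span_end, c.n_basic)
            for c in clusters
        ]
        assert got == naive_clusters(tail, CFG)


class TestAttachPhosphosites:
    def _cluster(self, tail):
        (cluster,) = merge_windows(scan_windows(tail, CFG), tail, CFG)
        return cluster

    def test_site_inside_window_attached(self):
        tail = make_tail("KRKRKRKRK" + "A" * 10 + "S" + "A" * 10)
        cluster = attach_phosphosites(self._cluster(tail), tail, CFG)
        assert ("S", 20) in cluster.phosphosites and cluster.qualifies_esm

    def test_flank_boundary_is_exactly_five(self):
        base = "KRKRKRKRK" + "A" * 21  # one window, union 1-30
        inside = make_tail(base + "A" * 4 + "S" + "A" * 5)  # S at 35
        cluster = attach_phosphosites(self._cluster(inside), inside, CFG)
        assert ("S", 35) in cluster.phosphosites
        outside = make_tail(base + "A" * 5 + "S" + "A" * 4)  # S at 36
        cluster = attach_phosphosites(self._cluster(outside), outside, CFG)
        assert cluster.phosphosites == [] and not cluster.qualifies_esm

    def test_flank_clipped_to_tail(self):
        # C-tail beginning right after a TM helix: flank cannot reach into it
        tail = make_tail("KRKRKRKRK" + "A" * 21, terminus="C", start=101)
        cluster = attach_phosphosites(self._cluster(tail), tail, CFG)
        positions = [pos for _, pos in cluster.phosphosites]
        assert all(pos >= 101 for pos in positions)

    def test_curated_sites_intersect_not_substitute(self):
        tail = make_tail("KRKRKRKRK" + "ASA" + "S" + "A" * 17)
        cluster = self._cluster(tail)
        both = attach_phosphosites(cluster, tail, CFG)
        assert {pos for _, pos in both.phosphosites} == {11, 13}
        curated = attach_phosphosites(cluster, tail, CFG, curated_sites={13})
        assert [pos for _, pos in curated.phosphosites] == [13]
        # curation cannot invent a site the sequence does not predict
        invented = attach_phosphosites(cluster, tail, CFG, curated_sites={5})
        assert invented.phosphosites == []

    def test_x_is_never_basic_or_phospho(self):
        tail = make_tail("KRKRKRKR" + "X" + "A" * 21)
        assert scan_windows(tail, CFG) == []  # 8 basics + X
        assert kr_density(tail) == pytest.approx(8 / 30)


class TestTailMetrics:
    def test_kr_density_examples(self):
        assert kr_density(make_tail("K" * 9 + "A" * 21)) == pytest.approx(0.3)
        assert kr_density(make_tail("A" * 40)) == 0.0
        assert kr_density(make_tail("K" * 17)) == 1.0

    def test_appending_non_basic_strictly_decreases_density(self):
        tail = make_tail("KRKRA" * 4)
        longer = make_tail("KRKRA" * 4 + "S")
        assert kr_density(longer) < kr_density(tail)

    def test_net_charge_no_titratable_side_chains(self):
        assert net_tail_charge("AAAA", 7.0) == 0.0

    def test_net_charge_at_pka_is_half(self):
        assert net_tail_charge("D", 3.9) == pytest.approx(-0.5)

    def test_net_charge_matches_henderson_hasselbalch_oracle(self):
        # independent closed form for K side chains (pKa 10.5)
        expected = 4 * (1.0 / (1.0 + 10 ** (7.0 - 10.5)))
        assert net_tail_charge("KKKK", 7.0) == pytest.approx(expected)

    def test_mixed_sequence_charge(self):
        oracle = (
            1 / (1 + 10 ** (7 - 10.5))   # K
            + 1 / (1 + 10 ** (7 - 12.5))  # R
            - 1 / (1 + 10 ** (3.9 - 7))   # D
            - 1 / (1 + 10 ** (10.1 - 7))  # Y
        )
        assert net_tail_charge("KRDY", 7.0) == pytest.approx(oracle)


def planted_protein(n_plant=True, with_phospho=True, k=9):
    """80-residue N-tail with an optional planted cluster, 2 TMs, 40-residue C-tail."""
    n_tail = ["A"] * 80
    if n_plant:
        for i in range(10, 10 + k):
            n_tail[i] = "K"
        if with_phospho:
            n_tail[10 + k + 1] = "S"
    seq = "".join(n_tail) + "L" * 21 + "G" * 10 + "L" * 21 + "A" * 40
    record = ProteinRecord("p1", seq)
    annotation = TopologyAnnotation(
        "p1",
        [
            ("inside", 1, 80),
            ("TMhelix", 81, 101),
            ("outside", 102, 111),
            ("TMhelix", 112, 132),
            ("inside", 133, 172),
        ],
    )
    return record, annotation


class TestScreenProtein:
    def test_planted_n_candidate(self):
        n_res, c_res = screen_protein(*planted_protein())
        assert n_res.is_candidate and not c_res.is_candidate
        (cluster,) = [c for c in n_res.clusters if c.qualifies_esm]
        assert cluster.n_basic == 9

    def test_cluster_without_phosphosite_is_not_candidate(self):
        n_res, _ = screen_protein(*planted_protein(with_phospho=False))
        assert n_res.clusters and not n_res.is_candidate

    def test_short_tails_flagged_excluded(self):
        seq = "A" * 10 + "L" * 21 + "G" * 5 + "L" * 21 + "A" * 10
        record = ProteinRecord("p1", seq)
        annotation = TopologyAnnotation(
            "p1",
            [
                ("inside", 1, 10),
                ("TMhelix", 11, 31),
                ("outside", 32, 36),
                ("TMhelix", 37, 57),
                ("inside", 58, 67),
            ],
        )
        n_res, c_res = screen_protein(record, annotation)
        for res in (n_res, c_res):
            assert not res.is_candidate
            assert "shorter than window" in res.exclusion_reason

    def test_non_cytoplasmic_tail_reported_but_ineligible(self):
        record, annotation = planted_protein()
        flipped = TopologyAnnotation(
            "p1",
            [("outside", 1, 80)] + list(annotation.regions[1:]),
        )
        n_res, _ = screen_protein(record, flipped)
        assert not n_res.is_candidate
        assert "not cytoplasmic" in n_res.exclusion_reason
        assert n_res.kr_density > 0  # metrics still reported

    def test_widening_flank_never_removes_a_candidate(self):
        record, annotation = planted_protein()
        narrow = screen_protein(record, annotation, ScreenConfig(phospho_flank=5))
        wide = screen_protein(record, annotation, ScreenConfig(phospho_flank=10))
        assert wide[0].is_candidate >= narrow[0].is_candidate

    def test_restricting_phospho_residues_is_configurable(self):
        # the cluster's only site is a serine: the S/Y reading still finds it,
        # a T-only reading does not
        record, annotation = planted_protein()
        sy = screen_protein(record, annotation,
                            ScreenConfig(phospho_residues=frozenset("SY")))
        t_only = screen_protein(record, annotation,
                                ScreenConfig(phospho_residues=frozenset("T")))
        assert sy[0].is_candidate and not t_only[0].is_candidate


class TestScreenProteome:
    def test_counts_and_dedup_on_both_termini(self):
        rec, anno = planted_protein()
        # plant a C-terminal cluster too
        seq = list(rec.sequence)
        for i in range(140, 149):
            seq[i] = "R"
        seq[150] = "S"
        rec_both = ProteinRecord("p1", "".join(seq))
        table = screen_proteome([rec_both], {"p1": anno})
        assert table.summary["both"] == 1
        assert table.summary["unique_candidates"] == 1
        assert table.summary["n_only"] == 0 and table.summary["c_only"] == 0

    def test_missing_topology_goes_to_unscreened(self):
        rec, anno = planted_protein()
        orphan = ProteinRecord("p2", "A" * 50)
        table = screen_proteome([rec, orphan], {"p1": anno})
        assert table.unscreened == ["p2"]
        assert set(table.table.protein_id) == {"p1"}

    def test_known_candidates_subtracted_from_additional(self):
        rec, anno = planted_protein()
        with_known = screen_proteome([rec], {"p1": anno}, known_candidates={"p1"})
        without = screen_proteome([rec], {"p1": anno})
        assert with_known.summary["additional_candidates"] == 0
        assert without.summary["additional_candidates"] == 1

    def test_rows_in_input_order_n_before_c(self):
        rec1, anno1 = planted_protein()
        rec2 = ProteinRecord("zz", rec1.sequence)
        anno2 = TopologyAnnotation("zz", list(anno1.regions))
        table = screen_proteome([rec2, rec1], {"p1": anno1, "zz": anno2})
        assert list(table.table.protein_id) == ["zz", "zz", "p1", "p1"]
        assert list(table.table.terminus) == ["N", "C", "N", "C"]
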