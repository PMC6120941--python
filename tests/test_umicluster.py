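"""Core clustering method: Levenshtein merging, chaining, collapsing, shifts."""

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from umishift import (
    PositionKey,
    UmishiftError,
    classify_strict_shift,
    cluster_alignments,
    collapse,
    find_clusters,
    levenshtein,
    merge_umis_at_position,
    pooled_shift_distribution,
    summarize,
)
from umishift.umicluster import UmiReadCluster, build_position_index

from .conftest import (
    brute_force_components,
    brute_force_levenshtein,
    make_fig1_alignments,
    random_coordinate_instance,
)


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("AAAGGAGTGG", "AAAGGAGTGG", 0),
            ("AAAGGAGTGG", "AAAGGAGTGC", 1),
            ("AAA", "AGAA", 1),  # single insertion
            ("", "ACGT", 4),
            ("AC", "CA", 2),
        ],
    )
    def test_known_distances(self, a, b, expected):
        assert levenshtein(a, b) == expected

    @given(
        st.text(alphabet="ACGTN", max_size=12),
        st.text(alphabet="ACGTN", max_size=12),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_dynamic_programming_oracle(self, a, b):
        d = levenshtein(a, b)
        assert d == brute_force_levenshtein(a, b)
        assert d == levenshtein(b, a)  # symmetry
        assert (d == 0) == (a == b)


class TestMergeUmis:
    def test_abundance_first_greedy_assignment(self):
        groups = merge_umis_at_position({"AAAA": 10, "AAAT": 2, "CCCC": 5})
        by_rep = {g.representative: g.count for g in groups}
        assert by_rep == {"AAAA": 12, "CCCC": 5}

    def test_single_umi_is_its_own_representative(self):
        (group,) = merge_umis_at_position({"ACGT": 3})
        assert group.representative == "ACGT" and group.count == 3

    def test_non_transitive_chain_stops_at_representative(self):
        # AATT is distance 2 from the representative AAAA even though it is
        # distance 1 from the member AAAT: membership tests the representative
        groups = merge_umis_at_position({"AAAA": 5, "AAAT": 5, "AATT": 1})
        by_rep = {g.representative: sorted(g.members) for g in groups}
        assert by_rep == {"AAAA": ["AAAA", "AAAT"], "AATT": ["AATT"]}

    def test_result_independent_of_input_iteration_order(self):
        counts = {"AAAA": 5, "AAAT": 5, "AATT": 1, "CCCC": 2, "CCCG": 2}
        items = list(counts.items())
        reference = None
        for seed in range(10):
            random.Random(seed).shuffle(items)
            groups = merge_umis_at_position(dict(items))
            snapshot = sorted((g.representative, sorted(g.members.items())) for g in groups)
            reference = reference or snapshot
            assert snapshot == reference

    def test_every_member_within_distance_one_of_representative(self):
        rng = np.random.default_rng(7)
        umis = {
            "".join(rng.choice(list("ACGT"), size=6)): int(rng.integers(1, 50))
            for _ in range(60)
        }
        for group in merge_umis_at_position(umis):
            assert all(
                levenshtein(m, group.representative) <= 1 for m in group.members
            )


class TestFindClusters:
    def test_worked_example_cluster(self):
        pairs = [(591514, 1), (591515, 10), (591516, 796), (591517, 3), (591518, 1)]
        (cluster,) = find_clusters(pairs, max_gap=3, umi="AAAGGAGTGG")
        assert cluster.size == 5
        assert cluster.total_reads == 811
        assert cluster.mode == 591516
        assert classify_strict_shift(cluster) == 1

    def test_gap_beyond_threshold_splits(self):
        clusters = find_clusters([(100, 1), (110, 1)], max_gap=3)
        assert [c.size for c in clusters] == [1, 1]

    def test_chaining_spans_more_than_max_gap(self):
        (cluster,) = find_clusters([(100, 1), (103, 1), (106, 1)], max_gap=3)
        assert cluster.size == 3  # single linkage: total span 6 bp is fine

    def test_unsorted_input_is_contract_error(self):
        with pytest.raises(UmishiftError):
            find_clusters([(100, 1), (90, 1)])

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_matches_connected_components_oracle(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        max_gap = data.draw(st.integers(0, 6))
        pairs = random_coordinate_instance(rng)
        clusters = find_clusters(pairs, max_gap)
        got = sorted(sorted(c.coordinates) for c in clusters)
        assert got == brute_force_components([c for c, _ in pairs], max_gap)
        # conservation: every read lands in exactly one cluster
        assert sum(c.total_reads for c in clusters) == sum(n for _, n in pairs)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_cluster_count_non_increasing_in_max_gap(self, seed):
        pairs = random_coordinate_instance(np.random.default_rng(seed))
        counts = [len(find_clusters(pairs, g)) for g in range(0, 8)]
        assert counts == sorted(counts, reverse=True)

    def test_max_gap_zero_degenerates_to_per_coordinate_counting(self):
        pairs = [(100, 4), (101, 2), (102, 9)]
        clusters = find_clusters(pairs, max_gap=0)
        assert all(c.size == 1 for c in clusters)
        assert [collapse(c).position.coordinate for c in clusters] == [100, 101, 102]


class TestStrictShiftAndCollapse:
    @pytest.mark.parametrize(
        "coords,expected",
        [
            ((591514, 591515, 591516, 591517, 591518), 1),
            ((100, 102, 104), 2),
            ((100, 101, 103), "mixed"),
            ((42,), "none"),
        ],
    )
    def test_classification(self, coords, expected):
        cluster = UmiReadCluster("A" * 10, "Chr1", "+", coords, (1,) * len(coords))
        assert classify_strict_shift(cluster) == expected

    def test_collapse_lands_on_mode(self):
        cluster = UmiReadCluster(
            "AAAGGAGTGG", "Chr03", "+",
            (591514, 591515, 591516, 591517, 591518), (1, 10, 796, 3, 1),
        )
        obs = collapse(cluster)
        assert obs.position == PositionKey("Chr03", "+", 591516)
        assert obs.total_reads == 811

    def test_modal_tie_breaks_leftmost(self):
        cluster = UmiReadCluster("AAAA", "c", "+", (10, 11, 12), (5, 5, 2))
        assert cluster.mode == 10


class TestShiftDistribution:
    def test_single_worked_example_cluster_density(self):
        (cluster,) = find_clusters(
            [(591514, 1), (591515, 10), (591516, 796), (591517, 3), (591518, 1)]
        )
        dist = pooled_shift_distribution([cluster])
        assert dist.pooled == {-2: 1, -1: 10, 0: 796, 1: 3, 2: 1}
        assert dist.density[0] == pytest.approx(796 / 811)

    def test_all_singletons_concentrate_at_zero(self):
        clusters = find_clusters([(100, 3), (200, 7)], max_gap=3)
        assert pooled_shift_distribution(clusters).density == {0: 1.0}

    def test_hand_pooled_two_clusters(self):
        a = UmiReadCluster("AAAA", "c", "+", (50,), (5,))
        b = UmiReadCluster("CCCC", "c", "+", (80, 81), (5, 5))
        dist = pooled_shift_distribution([a, b])
        assert dist.pooled == {0: 10, 1: 5}
        assert dist.density == pytest.approx({0: 2 / 3, 1: 1 / 3})

    def test_restriction_to_strict_n(self):
        s1 = UmiReadCluster("AAAA", "c", "+", (10, 11), (4, 1))
        s2 = UmiReadCluster("CCCC", "c", "+", (20, 22), (4, 1))
        dist = pooled_shift_distribution([s1, s2], restrict_to_strict=2)
        assert dist.pooled == {0: 4, 2: 1}

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_density_sums_to_one_and_peaks_at_zero(self, seed):
        pairs = random_coordinate_instance(np.random.default_rng(seed), max_n=50)
        dist = pooled_shift_distribution(find_clusters(pairs, 3))
        density = dist.density
        assert sum(density.values()) == pytest.approx(1.0, abs=1e-9)
        assert density[0] == max(density.values())

    def test_empty_cluster_set_reports_undefined_density(self):
        dist = pooled_shift_distribution([])
        assert dist.pooled == {} and dist.density == {}


class TestSummaryAndIndex:
    def test_hand_counted_proportions(self):
        clusters = [
            UmiReadCluster("AAAA", "c", "+", (10,), (4,)),
            UmiReadCluster("CCCC", "c", "+", (20,), (4,)),
            UmiReadCluster("GGGG", "c", "+", (30, 31), (10, 2)),
        ]
        s = summarize(clusters)
        assert s.clusters_by_size == {1: (2, 2 / 3), 2: (1, 1 / 3)}
        assert s.reads_by_size == {1: (8, 8 / 20), 2: (12, 12 / 20)}
        assert s.max_size == 2 and s.total_reads == 20

    def test_single_cluster_has_unit_proportions(self):
        s = summarize([UmiReadCluster("AAAA", "c", "+", (10,), (4,))])
        assert s.clusters_by_size[1] == (1, 1.0)
        assert s.reads_by_size[1] == (4, 1.0)

    def test_empty_set_gives_empty_tables(self):
        s = summarize([])
        assert s.clusters_by_size == {} and s.reads_by_size == {} and s.max_size == 0

    def test_index_separates_strands_and_merges_coordinates(self):
        groups = []
        for coord, strand in [(100, "+"), (105, "+"), (100, "-")]:
            (g,) = merge_umis_at_position(
                {"AAAA": 2}, PositionKey("c", strand, coord)
            )
            groups.append(g)
        index = build_position_index(groups)
        assert index[("c", "+", "AAAA")] == [(100, 2), (105, 2)]
        assert index[("c", "-", "AAAA")] == [(100, 2)]


class TestClusterAlignments:
    def test_worked_example_end_to_end(self):
        clusters = cluster_alignments(make_fig1_alignments())
        assert len(clusters) == 1
        assert clusters[0].size == 5 and clusters[0].total_reads == 811
        assert clusters[0].modal_sequence == "AC" * 18

    def test_umi_errors_at_one_coordinate_merge_into_cluster(self):
        alns = make_fig1_alignments()
        # one read at the mode with a 1-substitution UMI must merge in
        err = alns[500]
        alns[500] = type(err)(
            err.read_id, "AAAGGAGTGC", err.reference, err.strand,
            err.coordinate, err.sequence,
        )
        clusters = cluster_alignments(alns)
        assert len(clusters) == 1 and clusters[0].total_reads == 811

    def test_collapsed_count_never_exceeds_uncollapsed(self):
        rng = np.random.default_rng(11)
        alns = []
        for i in range(300):
            alns.append(
                type(make_fig1_alignments()[0])(
                    f"r{i}",
                    "".join(rng.choice(list("ACGT"), size=6)),
                    "c",
                    "+",
                    int(rng.integers(1, 60)),
                    "",
                )
            )
        clusters = cluster_alignments(alns, keep_sequences=False)
        n_collapsed = len(clusters)
        n_uncollapsed = sum(c.size for c in clusters)
        assert n_collapsed <= n_uncollapsed
        assert sum(c.total_reads for c in clusters) == 300
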