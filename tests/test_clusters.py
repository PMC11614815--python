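"""Cluster caller semantics, descriptors and oracle equivalence."""

import numpy as np
import pytest

from pirnakit.clusters import (
    call_clusters,
    classify_cluster_strand,
    count_htt_copies_in_clusters,
    cumulative_share,
    in_cluster_fraction,
    te_orientation_in_clusters,
)
from pirnakit.model import (
    ClusterCallParams,
    FeatureAnnotation,
    GenomicInterval,
    PiRNACluster,
)
from pirnakit.simulate import (
    DecoyRegion,
    HTTInsertion,
    PlantedCluster,
    SimulationConfig,
    simulate_genome,
    simulate_sample,
)

from conftest import clusters_as_dict, make_read, oracle_call_clusters

PARAMS = ClusterCallParams()


def reads_at(starts, length=30, strand="+", scaffold="s1"):
    return [
        make_read(scaffold=scaffold, start=int(s), length=length, strand=strand,
                  read_id=f"c{i}_{s}")
        for i, s in enumerate(starts)
    ]


class TestCallClusters:
    def test_no_reads_no_clusters(self):
        assert call_clusters([], {"s1": 100_000}, PARAMS) == []

    def test_empty_scaffold_sizes_is_an_error(self):
        with pytest.raises(ValueError, match="scaffold_sizes"):
            call_clusters([make_read()], {}, PARAMS)

    def test_read_past_scaffold_end_is_an_error(self):
        with pytest.raises(ValueError, match="past the end"):
            call_clusters([make_read(start=99_990)], {"s1": 100_000}, PARAMS)

    def test_dense_4kb_region_yields_one_containing_cluster(self):
        starts = np.linspace(40_000, 44_000 - 28, 300)
        reads = reads_at(starts, length=28)
        called = call_clusters(reads, {"s1": 100_000}, PARAMS)
        assert len(called) == 1
        c = called[0].interval
        assert c.start <= 40_000 and c.end >= 44_000
        # agrees with the brute-force enumeration
        assert clusters_as_dict(called) == oracle_call_clusters(
            reads, {"s1": 100_000}, PARAMS
        )

    def test_subthreshold_density_yields_nothing(self):
        # 20 reads across one 5 kb window: 4 reads/kb, below the threshold
        reads = reads_at(np.linspace(0, 4970, 20))
        assert call_clusters(reads, {"s1": 20_000}, PARAMS) == []

    def test_density_exactly_five_is_rejected_strict(self):
        # 25 reads with 5' ends in [0, 5000): density exactly 5.0/kb
        reads = reads_at(range(0, 5000, 200))
        assert len(reads) == 25
        assert call_clusters(reads, {"s1": 20_000}, PARAMS) == []
        # one more read tips the density over the threshold
        reads26 = reads + reads_at([100], length=30)
        called = call_clusters(reads26, {"s1": 20_000}, PARAMS)
        assert len(called) == 1

    def test_coverage_exactly_twelve_percent_passes(self):
        # 30 reads of 30 nt covering exactly 600 of 5000 bases (12%)
        starts = list(range(0, 580, 20)) + [570]
        reads = reads_at(starts, length=30)
        assert len(reads) == 30
        called = call_clusters(reads, {"s1": 20_000}, PARAMS)
        assert len(called) == 1
        # dropping the tail read leaves 590 covered bases (11.8%): rejected
        called_low = call_clusters(reads[:-1], {"s1": 20_000}, PARAMS)
        assert called_low == []

    def test_gap_exactly_20kb_stays_split_strict(self):
        region_a = reads_at(list(range(0, 580, 20)) + [570], length=30)
        region_b = reads_at(
            [29_000 + s for s in list(range(0, 580, 20)) + [570]], length=30
        )
        called = call_clusters(region_a + region_b, {"s1": 40_000}, PARAMS)
        # A spans [0, 5000), B [25000, 34000): separation exactly 20 kb
        assert clusters_as_dict(called) == {"s1": [(0, 5000), (25_000, 34_000)]}

    def test_gap_below_20kb_merges(self):
        region_a = reads_at(list(range(0, 580, 20)) + [570], length=30)
        region_b = reads_at(
            [28_000 + s for s in list(range(0, 580, 20)) + [570]], length=30
        )
        called = call_clusters(region_a + region_b, {"s1": 40_000}, PARAMS)
        assert clusters_as_dict(called) == {"s1": [(0, 33_000)]}

    def test_supra_threshold_regions_15kb_apart_merge_25kb_stay_split(self):
        dense = lambda off: reads_at(np.linspace(off, off + 1000, 60), length=28)
        near = call_clusters(dense(0) + dense(20_000), {"s1": 60_000}, PARAMS)
        assert len(near) == 1
        far = call_clusters(dense(0) + dense(30_000), {"s1": 60_000}, PARAMS)
        assert len(far) == 2

    def test_multimappers_excluded_by_default(self):
        starts = np.linspace(40_000, 44_000 - 28, 300)
        multi = [
            make_read(start=int(s), length=28, read_id=f"m{i}", mapping_count=2)
            for i, s in enumerate(starts)
        ]
        assert call_clusters(multi, {"s1": 100_000}, PARAMS) == []
        keep = ClusterCallParams(unique_only=False)
        assert len(call_clusters(multi, {"s1": 100_000}, keep)) == 1

    def test_deterministic_under_read_reordering(self):
        rng = np.random.default_rng(5)
        starts = rng.integers(10_000, 16_000, 200)
        reads = reads_at(starts)
        shuffled = list(reads)
        rng.shuffle(shuffled)
        a = call_clusters(reads, {"s1": 50_000}, PARAMS)
        b = call_clusters(shuffled, {"s1": 50_000}, PARAMS)
        assert [(c.interval, c.read_count, c.cluster_id) for c in a] == [
            (c.interval, c.read_count, c.cluster_id) for c in b
        ]

    def test_ranking_names_most_productive_first(self):
        big = reads_at(np.linspace(10_000, 12_000, 120))
        small = reads_at(np.linspace(40_000, 41_000, 60))
        called = call_clusters(big + small, {"s1": 100_000}, PARAMS)
        assert [c.cluster_id for c in called] == ["cluster_1", "cluster_2"]
        assert called[0].read_count > called[1].read_count
        assert called[0].interval.start < 13_000

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_on_seeded_simulations(self, seed):
        cfg = SimulationConfig(
            seed=seed,
            n_reads=2_500,
            genome=[("s1", 100_000)],
            clusters=[
                PlantedCluster("s1", 15_000, 30_000, "+", te_mix={"Mariner": 0.5}),
                PlantedCluster("s1", 62_000, 72_000, "-", te_mix={"Ty3": 0.5}),
            ],
            decoy_regions=[DecoyRegion("s1", 80_000, 95_000, density=2.0)],
            multimap_fraction=0.0,
        )
        genome, _, library, _ = simulate_sample(cfg)
        sizes = {k: len(v) for k, v in genome.items()}
        called = call_clusters(library.reads, sizes, PARAMS)
        assert clusters_as_dict(called) == oracle_call_clusters(
            library.reads, sizes, PARAMS
        )

    def test_monotonicity_in_density_and_merge_gap(self):
        cfg = SimulationConfig(seed=13, n_reads=2_000, genome=[("s1", 100_000)],
                               clusters=[PlantedCluster("s1", 10_000, 50_000, "+",
                                                        te_mix={"Mariner": 0.5})],
                               multimap_fraction=0.0)
        genome, _, library, _ = simulate_sample(cfg)
        sizes = {k: len(v) for k, v in genome.items()}
        n_by_density = [
            len(call_clusters(library.reads, sizes,
                              ClusterCallParams(min_density=d)))
            for d in (1.0, 5.0, 20.0, 60.0)
        ]
        assert n_by_density == sorted(n_by_density, reverse=True)
        n_by_gap = [
            len(call_clusters(library.reads, sizes, ClusterCallParams(merge_gap=g)))
            for g in (0, 5_000, 20_000, 80_000)
        ]
        assert n_by_gap == sorted(n_by_gap, reverse=True)


class TestStrandness:
    def _cluster(self):
        return PiRNACluster(
            "cluster_1", GenomicInterval("s1", 0, 10_000), 1.0, 0.0, 0.5, "unbiased"
        )

    @pytest.mark.parametrize(
        "n_plus,n_minus,expected",
        [
            (80, 20, "plus"),
            (50, 50, "unbiased"),
            (75, 25, "plus"),  # boundary counts as biased
            (25, 75, "minus"),
            (74, 26, "unbiased"),
        ],
    )
    def test_75_percent_rule(self, n_plus, n_minus, expected):
        reads = reads_at(range(100, 100 + n_plus * 40, 40), strand="+") + reads_at(
            range(5000, 5000 + n_minus * 40, 40), strand="-"
        )
        label, frac = classify_cluster_strand(self._cluster(), reads)
        assert label == expected
        assert frac == pytest.approx(n_plus / (n_plus + n_minus))

    def test_zero_support_is_an_error(self):
        with pytest.raises(ValueError, match="no supporting reads"):
            classify_cluster_strand(self._cluster(), [])


class TestCumulativeShare:
    def test_single_cluster(self):
        c = PiRNACluster("cluster_1", GenomicInterval("s1", 0, 5000), 42.0, 0, 0.5,
                         "unbiased")
        np.testing.assert_allclose(cumulative_share([c]), [1.0])

    def test_ten_equal_clusters(self):
        cs = [
            PiRNACluster(f"cluster_{i}", GenomicInterval("s1", i * 10_000,
                                                         i * 10_000 + 5000),
                         10.0, 0, 0.5, "unbiased")
            for i in range(1, 11)
        ]
        share = cumulative_share(cs)
        assert share[4] == pytest.approx(0.5)

    def test_matches_sort_and_cumsum_oracle(self):
        rng = np.random.default_rng(2)
        supports = rng.uniform(1, 500, size=30)
        cs = [
            PiRNACluster(f"cluster_{i}", GenomicInterval("s1", i * 6000,
                                                         i * 6000 + 5000),
                         float(s), 0, 0.5, "unbiased")
            for i, s in enumerate(supports, 1)
        ]
        expected = np.cumsum(np.sort(supports)[::-1]) / supports.sum()
        np.testing.assert_allclose(cumulative_share(cs), expected)


def _clusters_from_intervals(intervals):
    return [
        PiRNACluster(f"cluster_{i}", GenomicInterval("s1", s, e), 1.0, 0, 0.5,
                     "unbiased")
        for i, (s, e) in enumerate(intervals, 1)
    ]


class TestInClusterFraction:
    def test_all_inside_and_none_inside(self):
        clusters = _clusters_from_intervals([(0, 10_000)])
        inside = reads_at(range(100, 2100, 100))
        outside = reads_at(range(20_000, 22_000, 100))
        result = in_cluster_fraction(
            {"in": inside, "out": outside, "empty": []}, clusters
        )
        assert result["in"] == 1.0
        assert result["out"] == 0.0
        assert result["empty"] is None

    def test_planted_mixture_matches_membership_oracle(self):
        rng = np.random.default_rng(4)
        clusters = _clusters_from_intervals([(10_000, 20_000), (50_000, 60_000)])
        reads = reads_at(rng.integers(0, 80_000, size=400))
        (got,) = in_cluster_fraction({"g": reads}, clusters).values()
        expected = np.mean(
            [
                (10_000 <= r.five_prime < 20_000) or (50_000 <= r.five_prime < 60_000)
                for r in reads
            ]
        )
        assert got == pytest.approx(expected)


class TestHttCopies:
    def test_three_copies_one_inside(self):
        clusters = _clusters_from_intervals([(20_000, 30_000)])
        cfg = SimulationConfig(
            seed=1,
            genome=[("s1", 120_000)],
            clusters=[PlantedCluster("s1", 20_000, 30_000, "+",
                                     te_mix={"Mariner": 0.5})],
            htt_insertions=[
                HTTInsertion("OC1", "s1", 25_000),
                HTTInsertion("OC1", "s1", 60_000),
                HTTInsertion("OC1", "s1", 90_000),
            ],
            n_reads=100,
        )
        _, annotations = simulate_genome(cfg)
        htts = [a for a in annotations if a.is_htt]
        assert count_htt_copies_in_clusters(htts, clusters) == {"OC1": 1}

    def test_no_clusters_all_zeros(self):
        htt = FeatureAnnotation(
            GenomicInterval("s1", 100, 700, "+"), "TE", family="ET", name="e0",
            is_htt=True,
        )
        assert count_htt_copies_in_clusters([htt], []) == {"ET": 0}


class TestTeOrientation:
    def test_all_plus_is_plus_biased(self):
        clusters = _clusters_from_intervals([(0, 50_000)])
        tes = [
            FeatureAnnotation(GenomicInterval("s1", i * 2000, i * 2000 + 500, "+"),
                              "TE", family="Mariner", name=f"m{i}")
            for i in range(8)
        ]
        df = te_orientation_in_clusters(tes, clusters)
        assert df.loc[0, "bias"] == "plus"
        assert df.loc[0, "n_plus"] == 8 and df.loc[0, "n_minus"] == 0

    def test_balanced_is_unbiased(self):
        clusters = _clusters_from_intervals([(0, 50_000)])
        tes = [
            FeatureAnnotation(
                GenomicInterval("s1", i * 2000, i * 2000 + 500,
                                "+" if i % 2 else "-"),
                "TE", family="Mariner", name=f"m{i}")
            for i in range(12)
        ]
        df = te_orientation_in_clusters(tes, clusters)
        assert df.loc[0, "bias"] == "unbiased"
        assert df.loc[0, "n_plus"] == 6 and df.loc[0, "n_minus"] == 6
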