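from alfalign.align import AlignmentResult
from alfalign.mapper import MapperConfig, _make_extender
from alfalign.regions import (
    CandidateRegion,
    SchedulerCaps,
    SchedulerState,
    augment_region,
    build_regions,
    cluster_seeds,
    rank_regions,
    region_rescue,
    schedule_extensions,
)
from alfalign.seeds import Seed, SeedParams, collect_seeds



def _feasible(score=100):
    return AlignmentResult("+", 0, [("M", 100)], score=score, feasible=True)


class TestClusterSeeds:
    def test_single_seed_single_region(self):
        (region,) = cluster_seeds([Seed(0, 500, 30)], read_len=100)
        assert region.anchor == Seed(0, 500, 30)
        assert region.coverage == 30

    def test_far_apart_seeds_make_two_regions(self):
        seeds = [Seed(0, 1_000, 30), Seed(50, 9_000_000, 25)]
        regions = cluster_seeds(seeds, read_len=1000, text_len=10_000_000)
        assert len(regions) == 2

    def test_regions_are_pairwise_disjoint(self, rng):
        for _ in range(30):
            seeds = [
                Seed(rng.randrange(150), rng.randrange(5000), rng.randint(10, 40))
                for _ in range(rng.randint(1, 20))
            ]
            regions = cluster_seeds(seeds, read_len=200, text_len=6000)
            spans = sorted((r.ref_start, r.ref_end) for r in regions)
            for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
                assert b1 <= a2

    def test_coverage_bounded_by_read_length(self, rng):
        seeds = [Seed(i * 7 % 90, 100 + i * 13, 20) for i in range(12)]
        for region in cluster_seeds(seeds, read_len=100, text_len=5000):
            assert 0 <= region.coverage <= 100

    def test_planted_read_clusters_to_one_region(self, rng, genome_10k, index_10k):
        text = genome_10k.sequence
        origin = 4321
        read = list(text[origin : origin + 300])
        for p in (75, 150, 225):  # three scattered mismatches
            read[p] = "A" if read[p] != "A" else "C"
        read = "".join(read)
        seeds = [
            s
            for s in collect_seeds(index_10k, read, SeedParams(20, 1))
            if s.strand == "+"
        ]
        regions = cluster_seeds(seeds, len(read), text_len=len(text))
        containing = [r for r in regions if r.ref_start <= origin < r.ref_end]
        assert len(containing) == 1
        assert len(containing[0].seeds) >= 2

    def test_anchor_is_longest_seed_in_region(self, rng):
        seeds = [Seed(0, 1000, 35), Seed(40, 1040, 20), Seed(70, 1070, 25)]
        (region,) = cluster_seeds(seeds, read_len=120, text_len=5000)
        assert region.anchor.length == 35
        assert all(s.length <= region.anchor.length for s in region.seeds)


class TestAugment:
    def _region(self):
        (region,) = cluster_seeds([Seed(0, 1000, 40)], read_len=200, text_len=5000)
        return region

    def test_no_overlap_is_a_fixed_point(self):
        region = self._region()
        before = (list(region.seeds), region.coverage)
        augment_region(region, [Seed(50, 50_000 % 4000, 30)])
        assert (region.seeds, region.coverage) == before

    def test_overlapping_mem_increases_coverage(self):
        region = self._region()
        augment_region(region, [Seed(100, region.ref_start + 60, 30, occurrence_count=99)])
        assert region.coverage == 70

    def test_redundant_mem_leaves_coverage_unchanged(self):
        region = self._region()
        augment_region(region, [Seed(10, region.anchor.ref_start + 10, 20)])
        assert region.coverage == 40


class TestRanking:
    def test_by_coverage_then_anchor_then_position(self):
        r1 = CandidateRegion(0, 100, "+", [], Seed(0, 0, 30), coverage=120)
        r2 = CandidateRegion(200, 300, "+", [], Seed(0, 200, 50), coverage=300)
        r3 = CandidateRegion(400, 500, "+", [], Seed(0, 400, 40), coverage=120)
        ranked = rank_regions([r1, r2, r3])
        assert [r.coverage for r in ranked] == [300, 120, 120]
        assert ranked[1].anchor.length == 40  # longer anchor wins the tie

    def test_equal_everything_orders_by_ref_start(self):
        rs = [
            CandidateRegion(p, p + 50, "+", [], Seed(0, p, 30), coverage=90)
            for p in (900, 100, 500)
        ]
        assert [r.ref_start for r in rank_regions(rs)] == [100, 500, 900]


def _mk_region(coverage, ref_start=0, unique=False, anchor_len=30):
    return CandidateRegion(
        ref_start,
        ref_start + 100,
        "+",
        [],
        Seed(0, ref_start, anchor_len),
        coverage=coverage,
        has_unique_seed=unique,
    )


class TestScheduler:
    def test_halts_after_enough_feasible_alignments(self):
        regions = [_mk_region(100, i * 200) for i in range(10)]
        calls = []

        def extender(r):
            calls.append(r.ref_start)
            return [_feasible()] * 4

        caps = SchedulerCaps(max_feasible=4, max_failures=6, min_coverage_fraction=0.0)
        results = schedule_extensions(regions, extender, caps)
        assert len(calls) == 1
        assert len(results) == 4

    def test_halts_after_consecutive_failures(self):
        regions = [_mk_region(100, i * 200) for i in range(10)]
        calls = []

        def extender(r):
            calls.append(r.ref_start)
            return []

        caps = SchedulerCaps(max_feasible=16, max_failures=3, min_coverage_fraction=0.0)
        schedule_extensions(regions, extender, caps)
        assert len(calls) == 3

    def test_low_coverage_halts_but_unique_seed_region_still_extended(self):
        regions = [_mk_region(100, 0), _mk_region(10, 200), _mk_region(8, 400, unique=True)]
        calls = []

        def extender(r):
            calls.append(r.ref_start)
            return [_feasible()]

        caps = SchedulerCaps(max_feasible=16, max_failures=6, min_coverage_fraction=0.25)
        schedule_extensions(regions, extender, caps)
        assert calls == [0, 400]  # coverage-10 region skipped; unique one kept

    def test_state_counters(self):
        regions = [_mk_region(100, 0), _mk_region(90, 200)]
        state = SchedulerState()
        caps = SchedulerCaps(max_feasible=16, max_failures=6, min_coverage_fraction=0.0)
        schedule_extensions(regions, lambda r: [], caps, state)
        assert state.consecutive_failures == 2
        assert state.feasible_found == 0


class TestRescue:
    def test_normal_read_never_reaches_rescue(self, genome_100k, index_100k):
        text = genome_100k.sequence
        read = text[5000:6000]
        cfg = MapperConfig()
        params = cfg.seed_params(len(read), index_100k)
        oriented = {"+": read, "-": read}  # forward only matters here
        extender = _make_extender(index_100k, oriented, cfg)
        seeds = collect_seeds(index_100k, read, params)
        ranked = build_regions(
            seeds, len(read), text_len=index_100k.n_text, max_occurrences=10
        )
        caps = SchedulerCaps()
        assert schedule_extensions(ranked, extender, caps)

    def test_high_error_read_mapped_only_after_rescue(self, rng, genome_100k, index_100k):
        # 12% substitutions: above the default feasibility budget
        text = genome_100k.sequence
        origin = 20_000
        read = list(text[origin : origin + 1000])
        positions = rng.sample(range(1000), 120)
        for p in positions:
            read[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[p]]
        read = "".join(read)
        from alfalign.reference_io import reverse_complement

        cfg = MapperConfig()  # error budget 0.05 -> min score 500
        params = cfg.seed_params(len(read), index_100k)
        oriented = {"+": read, "-": reverse_complement(read)}
        extender = _make_extender(index_100k, oriented, cfg)
        seeds = collect_seeds(index_100k, read, params)
        ranked = build_regions(
            seeds, len(read), text_len=index_100k.n_text, max_occurrences=10
        )
        caps = SchedulerCaps()
        primary = schedule_extensions(ranked, extender, caps)
        assert primary == []  # score ~ 0.4*m is under the 0.5*m budget
        relaxed_cfg = MapperConfig(error_rate=0.12)
        rescue_extender = _make_extender(index_100k, oriented, relaxed_cfg)
        rescued = region_rescue(read, index_100k, params, rescue_extender, caps)
        assert rescued
        assert abs(rescued[0].ref_start - origin) <= 10

    def test_unmappable_read_stays_empty(self, index_100k):
        cfg = MapperConfig()
        read = "N" * 500
        params = SeedParams(20, 1)
        extender = lambda r: []
        caps = SchedulerCaps()
        assert region_rescue(read, index_100k, params, extender, caps) == []
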