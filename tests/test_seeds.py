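import pytest
from hypothesis import given, settings, strategies as st

from alfalign.index import build_index
from alfalign.reference_io import Reference, reverse_complement
from alfalign.seeds import (
    Seed,
    SeedParams,
    auto_min_seed_len,
    auto_query_step,
    collect_seeds,
    filter_smems,
    find_mems,
    seed_rescue,
)

from oracles import mem_oracle, smem_oracle, random_dna


def _ref(seq):
    return Reference.from_contigs([("c", seq)])


class TestAutoTuning:
    @pytest.mark.parametrize(
        "m,e,expected",
        [(1000, 0.05, 20), (10000, 0.02, 40), (100, 0.0, 40), (300, 0.1, 20)],
    )
    def test_min_seed_len_pigeonhole_with_clamp(self, m, e, expected):
        assert auto_min_seed_len(m, e) == expected

    @pytest.mark.parametrize(
        "s,L,expected", [(12, 40, 1), (4, 21, 3), (1, 20, 20), (1, 35, 35)]
    )
    def test_query_step_coprime_rule(self, s, L, expected):
        assert auto_query_step(s, L) == expected

    def test_query_step_detection_property(self, rng):
        # every MEM of length >= L must still be found at the auto step
        for _ in range(15):
            seq = random_dna(rng, rng.randint(300, 1500))
            ref = _ref(seq)
            s = rng.choice([1, 2, 3, 4])
            L = max(s, rng.choice([10, 14, 20]))
            i = rng.randrange(len(seq) - 120)
            read = list(seq[i : i + 100])
            for _ in range(3):
                read[rng.randrange(100)] = rng.choice("ACGT")
            read = "".join(read)
            idx = build_index(ref, s)
            q = auto_query_step(s, L)
            exp = mem_oracle(ref.sequence, read, L)
            got = {
                x.key()[1:]
                for x in find_mems(idx, read, SeedParams(L, q), count_occurrences=False)
            }
            assert got == exp


class TestFindMems:
    def test_worked_example(self):
        idx = build_index(_ref("TTTACGTACGAAA"), 1)
        seeds = find_mems(idx, "ACGTACG", SeedParams(3, 1))
        assert sorted((s.read_start, s.ref_start, s.length) for s in seeds) == [
            (0, 3, 7),
            (0, 7, 3),
            (3, 2, 4),
        ]

    def test_single_mem_example(self):
        idx = build_index(_ref("ACACACGT"), 1)
        seeds = find_mems(idx, "ACGT", SeedParams(3, 1))
        assert [(s.read_start, s.ref_start, s.length) for s in seeds] == [(0, 4, 4)]

    def test_no_shared_kmer_gives_empty(self):
        idx = build_index(_ref("AAAAAAAAAA"), 1)
        assert find_mems(idx, "CCCCCC", SeedParams(3, 1)) == []

    def test_read_shorter_than_min_len_gives_empty(self):
        idx = build_index(_ref("ACGTACGT"), 1)
        assert find_mems(idx, "ACG", SeedParams(5, 1)) == []

    def test_seeds_are_exact_and_maximal(self, rng, index_10k, genome_10k):
        text = genome_10k.sequence
        for _ in range(10):
            i = rng.randrange(9000)
            read = list(text[i : i + 200])
            for _ in range(6):
                read[rng.randrange(200)] = rng.choice("ACGT")
            read = "".join(read)
            for s in find_mems(index_10k, read, SeedParams(12, 1)):
                assert read[s.read_start : s.read_end] == text[s.ref_start : s.ref_end]
                if s.read_start > 0 and s.ref_start > 0:
                    left_r, left_t = read[s.read_start - 1], text[s.ref_start - 1]
                    assert left_r != left_t or left_r not in "ACGT"
                if s.read_end < len(read) and s.ref_end < len(text):
                    rr, rt = read[s.read_end], text[s.ref_end]
                    assert rr != rt or rr not in "ACGT"

    @pytest.mark.parametrize("s", [1, 4, 12])
    def test_oracle_equivalence_random_instances(self, s, rng):
        for _ in range(10):
            seq = random_dna(rng, rng.randint(500, 4000))
            ref = _ref(seq)
            L = max(s, 13)
            i = rng.randrange(len(seq) - 250)
            read = list(seq[i : i + 220])
            for _ in range(7):
                read[rng.randrange(220)] = rng.choice("ACGT")
            read = "".join(read)
            idx = build_index(ref, s)
            got = {
                (x.read_start, x.ref_start, x.length)
                for x in find_mems(idx, read, SeedParams(L, 1), count_occurrences=False)
            }
            assert got == mem_oracle(ref.sequence, read, L)

    def test_reverse_strand_seeds_match_reverse_complement(self, index_10k, genome_10k, rng):
        text = genome_10k.sequence
        i = rng.randrange(9000)
        read = reverse_complement(text[i : i + 150])
        seeds = collect_seeds(index_10k, read, SeedParams(20, 1))
        rev = [s for s in seeds if s.strand == "-"]
        assert rev
        rc = reverse_complement(read)
        for s in rev:
            assert rc[s.read_start : s.read_end] == text[s.ref_start : s.ref_end]

    def test_unique_seed_has_occurrence_count_one(self, index_10k, genome_10k):
        text = genome_10k.sequence
        read = text[500:560]
        (seed,) = find_mems(index_10k, read, SeedParams(30, 1))
        assert seed.occurrence_count == 1


class TestSmemFilter:
    def test_worked_example(self):
        mems = [Seed(0, 3, 7), Seed(0, 7, 3), Seed(3, 2, 4)]
        smems = filter_smems(mems)
        assert [(s.read_start, s.ref_start, s.length) for s in smems] == [(0, 3, 7)]
        assert all(s.is_smem for s in smems)

    def test_single_mem_is_smem(self):
        assert len(filter_smems([Seed(5, 10, 8)])) == 1

    def test_disjoint_intervals_both_kept(self):
        mems = [Seed(0, 10, 5), Seed(5, 100, 5)]
        assert len(filter_smems(mems)) == 2

    def test_identical_read_intervals_all_kept(self):
        mems = [Seed(2, 10, 6), Seed(2, 50, 6)]
        assert len(filter_smems(mems)) == 2

    def test_matches_pairwise_containment_oracle(self, rng):
        for _ in range(25):
            mems = [
                Seed(rng.randrange(50), rng.randrange(500), rng.randint(1, 30))
                for _ in range(rng.randint(1, 15))
            ]
            exp = smem_oracle({(s.read_start, s.ref_start, s.length) for s in mems})
            got = {(s.read_start, s.ref_start, s.length) for s in filter_smems(mems)}
            assert got == exp

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 40), st.integers(0, 300), st.integers(1, 25)
            ),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_idempotent_and_order_independent(self, triples):
        mems = [Seed(a, b, c) for a, b, c in set(triples)]
        once = {s.key() for s in filter_smems(mems)}
        twice = {s.key() for s in filter_smems(filter_smems(mems))}
        shuffled = {s.key() for s in filter_smems(list(reversed(mems)))}
        assert once == twice == shuffled


class TestRescue:
    def test_finds_seeds_one_level_down(self, rng):
        # plant errors every L-2 bases so no stretch reaches L
        seq = random_dna(rng, 4000)
        ref = _ref(seq)
        idx = build_index(ref, 1)
        L = 24
        i = 1000
        read = list(seq[i : i + 240])
        for p in range(L - 2, len(read), L - 2):
            read[p] = "N"  # N never matches: hard break
        read = "".join(read)
        params = SeedParams(L, 1)
        assert find_mems(idx, read, params) == []
        rescued = seed_rescue(idx, read, params)
        assert rescued
        assert all(s.length >= 10 for s in rescued)

    def test_all_n_read_stays_empty(self, index_10k):
        params = SeedParams(20, 1)
        assert seed_rescue(index_10k, "N" * 100, params) == []

    def test_not_needed_for_exact_read(self, index_10k, genome_10k):
        read = genome_10k.sequence[100:300]
        params = SeedParams(20, 1)
        assert find_mems(index_10k, read, params)
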