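import pytest

from alfalign.align import (
    AlignmentResult,
    ScoringScheme,
    banded_align,
    bridge_gap,
    chain_guided_align,
    compute_mapq,
    full_length_align,
    min_feasible_score,
    rescore_cigar,
)
from alfalign.chains import ChainParams, enumerate_chains
from alfalign.index import build_index
from alfalign.reference_io import Reference
from alfalign.seeds import SeedParams, find_mems

from oracles import gotoh_glocal, gotoh_local, random_dna

SC = ScoringScheme()


class TestBandedAlign:
    def test_identity(self):
        a = banded_align("ACGTACGT", "ACGTACGT", 4, SC)
        assert (a.score, a.cigar_string, a.edit_distance) == (8, "8M", 0)

    def test_single_substitution_forced(self):
        a = banded_align("ACGT", "AGGT", 4, SC)
        assert (a.score, a.cigar_string, a.edit_distance) == (-1, "4M", 1)

    def test_full_band_equals_unbanded_oracle(self, rng):
        for _ in range(40):
            n, m = rng.randint(1, 120), rng.randint(1, 100)
            ref, read = random_dna(rng, n), random_dna(rng, m)
            a = banded_align(ref, read, max(m, n) + 1, SC)
            assert a.score == gotoh_glocal(ref, read)
            s2, nm2 = rescore_cigar(ref, a.ref_start, read, a.cigar, SC)
            assert (s2, nm2) == (a.score, a.edit_distance)

    def test_local_mode_matches_smith_waterman_and_never_negative(self, rng):
        scl = ScoringScheme(mode="local")
        for _ in range(30):
            n, m = rng.randint(1, 90), rng.randint(1, 70)
            ref, read = random_dna(rng, n), random_dna(rng, m)
            a = banded_align(ref, read, max(m, n) + 1, scl)
            assert a.score == gotoh_local(ref, read)
            assert a.score >= 0

    def test_narrow_band_never_beats_unbanded(self, rng):
        for _ in range(20):
            ref, read = random_dna(rng, 80), random_dna(rng, 60)
            a = banded_align(ref, read, 3, SC)
            assert a.score <= gotoh_glocal(ref, read)

    def test_end_to_end_has_no_soft_clips(self, rng):
        ref, read = random_dna(rng, 100), random_dna(rng, 60)
        a = banded_align(ref, read, 101, SC)
        assert all(op != "S" for op, _ in a.cigar)


class TestBridgeGap:
    @pytest.mark.parametrize(
        "rg,qg,expected",
        [
            ("G", "G", ([("M", 1)], 1, 0)),
            ("GA", "", ([("D", 2)], -8, 2)),
            ("", "TT", ([("I", 2)], -8, 2)),
            ("GATTC", "GTAC", None),
            ("GAT", "GCT", ([("M", 3)], -2, 1)),
            ("ACGTT", "ACG", ([("M", 3), ("D", 2)], -5, 2)),
            ("TT", "AATT", ([("I", 2), ("M", 2)], -6, 2)),
        ],
    )
    def test_recognized_patterns(self, rg, qg, expected):
        assert bridge_gap(rg, qg, SC) == expected

    def test_bridge_score_is_self_consistent(self, rng):
        for _ in range(60):
            rg = random_dna(rng, rng.randint(0, 8))
            qg = random_dna(rng, rng.randint(0, 8))
            res = bridge_gap(rg, qg, SC)
            if res is None:
                continue
            ops, score, nm = res
            s2, nm2 = rescore_cigar(rg, 0, qg, ops, SC)
            assert (s2, nm2) == (score, nm)
            assert sum(n for op, n in ops if op in "MI") == len(qg)
            assert sum(n for op, n in ops if op in "MD") == len(rg)


class TestChainGuided:
    def _plant(self, rng, genome_len=4000, read_len=400, n_sub=0, deletion=None):
        seq = random_dna(rng, genome_len)
        origin = rng.randrange(genome_len - read_len - 100)
        template = seq[origin : origin + read_len + (deletion or 0)]
        if deletion:
            cut = read_len // 2
            template = template[:cut] + template[cut + deletion :]
        read = list(template[:read_len])
        for _ in range(n_sub):
            read[rng.randrange(len(read))] = rng.choice("ACGT")
        return seq, origin, "".join(read)

    def _best_chain(self, ref, read, min_len=20):
        idx = build_index(ref, 4)
        seeds = find_mems(idx, read, SeedParams(min_len, 1))
        chains = enumerate_chains(seeds, ChainParams())
        return chains[0]

    def test_error_free_read_is_all_match(self, rng):
        seq, origin, read = self._plant(rng)
        ref = Reference.from_contigs([("c", seq)])
        chain = self._best_chain(ref, read)
        a = chain_guided_align(chain, ref.sequence, read, SC)
        assert a.cigar_string == f"{len(read)}M"
        assert a.score == len(read)
        assert a.ref_start == origin

    def test_planted_deletion_appears_in_cigar(self, rng):
        seq, origin, read = self._plant(rng, deletion=10)
        ref = Reference.from_contigs([("c", seq)])
        chain = self._best_chain(ref, read)
        a = chain_guided_align(chain, ref.sequence, read, SC)
        assert ("D", 10) in a.cigar
        assert a.edit_distance == 10

    def test_score_never_exceeds_unbanded_dp(self, rng):
        for _ in range(15):
            seq, origin, read = self._plant(rng, n_sub=8)
            ref = Reference.from_contigs([("c", seq)])
            chain = self._best_chain(ref, read)
            a = chain_guided_align(chain, ref.sequence, read, SC)
            window = ref.sequence[max(0, a.ref_start - 30) : a.ref_end + 30]
            assert a.score <= gotoh_glocal(window, read)
            s2, nm2 = rescore_cigar(ref.sequence, a.ref_start, read, a.cigar, SC)
            assert (s2, nm2) == (a.score, a.edit_distance)

    def test_full_length_matches_chain_guided_on_clean_read(self, rng):
        seq, origin, read = self._plant(rng)
        ref = Reference.from_contigs([("c", seq)])
        chain = self._best_chain(ref, read)
        a = chain_guided_align(chain, ref.sequence, read, SC)
        lo, hi = max(0, origin - 60), origin + len(read) + 60
        b = full_length_align(
            ref.sequence[lo:hi], read, SC, window_start=lo
        )
        assert (a.score, a.ref_start) == (b.score, b.ref_start)

    def test_band_excluding_the_true_path_gives_infeasible_not_a_crash(self, rng):
        # a 75-base insertion and a 75-base deletion 150 bases apart: the
        # true path detours 75 diagonals off-corner, beyond the error-budget
        # band of full_length_align (ceil(0.05*565)+5 = 34)
        seq = random_dna(rng, 4000)
        o = 1000
        read = (
            seq[o : o + 140]
            + random_dna(rng, 75)
            + seq[o + 140 : o + 290]
            + seq[o + 365 : o + 565]
        )
        window = seq[o : o + 565]
        b = full_length_align(window, read, SC, window_start=o)
        assert not b.feasible
        # the unbanded optimum is feasible, so the band alone caused the miss
        from alfalign.align import min_feasible_score

        assert gotoh_glocal(window, read) >= min_feasible_score(len(read), SC, 0.05)


class TestMapq:
    def test_unique_alignment_gets_60(self):
        best = AlignmentResult("+", 0, [("M", 100)], score=100, feasible=True)
        assert compute_mapq(best, None, 100) == 60

    def test_tied_scores_get_zero(self):
        best = AlignmentResult("+", 0, [("M", 100)], score=100, feasible=True)
        assert compute_mapq(best, 100, 100) == 0

    def test_half_margin_gets_30(self):
        best = AlignmentResult("+", 0, [("M", 100)], score=100, feasible=True)
        assert compute_mapq(best, 50, 100) == 30


class TestFeasibility:
    def test_threshold_floor(self):
        # at high error budgets the floor clamp takes over
        assert min_feasible_score(1000, SC, 0.10) == pytest.approx(300.0)

    def test_threshold_at_default_budget(self):
        assert min_feasible_score(1000, SC, 0.05) == pytest.approx(500.0)
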