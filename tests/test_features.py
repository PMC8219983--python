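"""Trimming, redundancy removal, U features and stability scoring."""

import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

from slofe.discovery import StemLoop
from slofe.errors import EmptyStemLoopError
from slofe.features import (
    attach_scores,
    deduplicate,
    select_stable,
    stability_scores,
    trim_flanks,
    u_features,
)
from slofe.io import GenomeRecord, revcomp


def make_sl(start, end, strand="+", dg=-10.0, seq=None, structure=None, contig="c"):
    n = end - start + 1
    if seq is None:
        seq = ("GC" * n)[:n]
    if structure is None:
        k = (n - 4) // 2
        structure = "(" * k + "." * (n - 2 * k) + ")" * k
    return StemLoop(f"SL_{contig}_{start}_{end}_{strand}", contig, start, end,
                    strand, seq, structure, dg)


class TestTrimFlanks:
    def test_quoted_rule(self):
        sl = make_sl(10, 24, seq="AAGGGGAAAACCCCA", structure="..((((....)))).")
        t = trim_flanks(sl)
        assert (t.start, t.end) == (12, 23)
        assert t.structure == "((((....))))"
        assert t.sequence == "GGGGAAAACCCC"

    def test_minus_strand_coordinates(self):
        # sequence is read 5'->3' on the minus strand: leading dots trim the
        # genomic *end*, trailing dots trim the genomic *start*
        sl = make_sl(10, 24, strand="-", seq="AAGGGGAAAACCCCA",
                     structure="..((((....)))).")
        t = trim_flanks(sl)
        assert (t.start, t.end) == (11, 22)

    def test_already_trimmed_unchanged(self):
        sl = make_sl(5, 16, seq="GGGGAAAACCCC", structure="((((....))))")
        assert trim_flanks(sl) == sl

    def test_all_dot_structure_rejected(self):
        sl = make_sl(5, 10, seq="AAAAAA", structure="......")
        with pytest.raises(EmptyStemLoopError):
            trim_flanks(sl)

    @given(st.integers(0, 4), st.integers(0, 4), st.integers(2, 6), st.integers(3, 6))
    def test_idempotent(self, lead, trail, stem, loop):
        n = lead + trail + 2 * stem + loop
        structure = "." * lead + "(" * stem + "." * loop + ")" * stem + "." * trail
        seq = "A" * lead + "G" * stem + "A" * loop + "C" * stem + "A" * trail
        sl = StemLoop("SL_c_1_%d_+" % n, "c", 1, n, "+", seq, structure, -8.0)
        once = trim_flanks(sl)
        assert trim_flanks(once) == once


class TestDeduplicate:
    def test_identical_sls_keep_one(self):
        a = make_sl(10, 29)
        assert deduplicate([a, dataclasses.replace(a)]) == [a]

    def test_partial_overlap_keeps_lower_dg(self):
        """80% overlap: the -10 survives, the -7 (closer to zero) is dropped."""
        a = make_sl(10, 29, dg=-10.0)
        b = make_sl(14, 33, dg=-7.0, seq="AT" * 10)
        assert deduplicate([a, b]) == [a]
        assert deduplicate([b, a]) == [a]

    def test_contained_span_is_dropped(self):
        outer = make_sl(10, 39, dg=-9.0)
        inner = make_sl(15, 30, dg=-7.0, seq="TA" * 8)
        assert deduplicate([inner, outer]) == [outer]

    def test_opposite_strands_do_not_conflict(self):
        a = make_sl(10, 29, dg=-10.0)
        b = make_sl(10, 29, dg=-7.0, strand="-")
        assert deduplicate([a, b]) == [a, b]

    def test_dg_floor_boundary(self):
        """dG = -4.9 removed, dG = -5.1 kept: 'less than -5' is strict."""
        kept = make_sl(10, 29, dg=-5.1)
        removed = make_sl(50, 69, dg=-4.9)
        boundary = make_sl(90, 109, dg=-5.0)
        assert deduplicate([kept, removed, boundary]) == [kept]

    def test_idempotent_and_order_insensitive(self, rng):
        sls = []
        pos = 10
        for i in range(30):
            length = int(rng.integers(16, 30))
            sls.append(make_sl(pos, pos + length - 1, dg=float(-rng.uniform(5.1, 30))))
            pos += int(rng.integers(4, 40))
        once = deduplicate(sls)
        assert deduplicate(once) == once
        perm = [sls[i] for i in rng.permutation(len(sls))]
        assert deduplicate(perm) == once


class TestUFeatures:
    def _genome_with_window(self, window_dna):
        # hairpin at 11..26, window immediately 3'
        seq = "A" * 10 + "GGGGGG" + "AAAA" + "CCCCCC" + window_dna + "A" * 10
        return GenomeRecord("c", seq), make_sl(
            11, 26, seq="GGGGGGAAAACCCCCC", structure="((((((....))))))"
        )

    @pytest.mark.parametrize(
        "window,polyu,ucontent,tail",
        [
            ("TTTTTTTGCA", 7, 7, "downstream"),
            ("TTTTTTAGCA", 6, 6, "downstream"),
            ("GACGACGACG", 0, 0, "none"),
            ("TTATAGCTAC", 2, 4, "discontinuous"),
            ("TTTATTAGCA", 3, 5, "discontinuous"),
            ("ATATTTTAGC", 4, 5, "none"),  # run of 4 but starting late
        ],
    )
    def test_window_features(self, window, polyu, ucontent, tail):
        genome, sl = self._genome_with_window(window)
        uf = u_features(sl, genome)
        assert (uf.polyU_len, uf.U_content, uf.tail_position) == (polyu, ucontent, tail)

    def test_window_clipped_at_contig_end(self):
        seq = "A" * 10 + "GGGGGG" + "AAAA" + "CCCCCC" + "TTT"
        sl = make_sl(11, 26, seq="GGGGGGAAAACCCCCC", structure="((((((....))))))")
        uf = u_features(sl, GenomeRecord("c", seq))
        assert uf.window == "UUU" and uf.U_content == 3

    def test_upstream_tail_from_stem_u(self):
        """>=4 U paired in the lower (tail-proximal) 40% of the 3' stem side."""
        seq5 = "AAAAAGGGGGG"
        seq3 = "CCCCCCTTTTT"  # tail-proximal stem positions carry the U run
        structure = "(" * 8 + "." * 6 + ")" * 8
        sl = make_sl(11, 32, seq=(seq5 + seq3), structure=structure)
        genome = GenomeRecord("c", "A" * 10 + seq5 + seq3 + "GACGACGACG" + "A" * 5)
        uf = u_features(sl, genome)
        assert uf.tail_position == "upstream"

    def test_strand_correctness_under_mirroring(self, fixture):
        """Mirroring the genome yields identical U features for mirrored SLs."""
        from slofe.discovery import discover
        from slofe.features import trim_flanks

        genome = fixture.genome
        mirrored = GenomeRecord(genome.id, revcomp(genome.sequence))
        n = genome.length
        sls = [trim_flanks(sl) for sl in discover(genome)][:40]
        for sl in sls:
            twin = dataclasses.replace(
                sl,
                start=n + 1 - sl.end,
                end=n + 1 - sl.start,
                strand="+" if sl.strand == "-" else "-",
            )
            assert u_features(sl, genome) == u_features(twin, mirrored)


class TestStabilityScores:
    def test_arithmetic(self):
        sl = make_sl(1, 26, dg=-20.0, seq="G" * 8 + "A" * 10 + "C" * 8,
                     structure="(" * 8 + "." * 10 + ")" * 8)
        s = stability_scores(sl)
        assert s.S1 == -20.0
        assert s.S2 == pytest.approx(-20.0 / 26)
        assert s.S3 == pytest.approx(-160.0)
        assert s.S4 == pytest.approx(-20.0 * 8 / 26, abs=1e-3)  # ~ -6.154

    def test_zero_dg_gives_zero_scores(self):
        sl = make_sl(1, 16, dg=0.0)
        s = stability_scores(sl)
        assert (s.S1, s.S2, s.S3, s.S4) == (0.0, 0.0, 0.0, 0.0)

    def test_cohort_of_one_normalizes_to_one(self):
        scored = attach_scores([make_sl(1, 20, dg=-12.0)])
        assert scored[0].S4_norm == 1.0


class TestSelectStable:
    def _cohort(self):
        # S4 values proportional to dG here (same geometry)
        return attach_scores(
            [make_sl(1 + 40 * i, 20 + 40 * i, dg=dg) for i, dg in
             enumerate([-30.0, -21.0, -9.0])]
        )

    def test_normalized_threshold(self):
        sls = self._cohort()
        kept = select_stable(sls, "S4", 0.6)
        assert [sl.dG for sl in kept] == [-30.0, -21.0]

    def test_zero_threshold_keeps_all(self):
        sls = self._cohort()
        assert select_stable(sls, "S4", 0.0) == sls

    def test_monotone_in_threshold(self):
        sls = self._cohort()
        sizes = [len(select_stable(sls, "S4", t / 10)) for t in range(11)]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_cohort(self):
        assert select_stable([], "S4", 0.6) == []
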