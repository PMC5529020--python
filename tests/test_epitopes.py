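"""MSA anchoring, shared segments, core motifs and mismatch-tolerant sums."""

import numpy as np
import pytest

from epimap import (
    SignalProfile,
    collect_similar,
    extract_core_motif,
    find_shared_segments,
    map_profiles_to_msa,
)
from epimap.library import STANDARD_RESIDUES


def profile(acc, scores):
    arr = np.asarray(scores, dtype=float)
    return SignalProfile(accession=acc, scores=arr, raw=arr)


def random_seq(rng, n):
    return "".join(rng.choice(list(STANDARD_RESIDUES), size=n))


class TestMapToMsa:
    def test_gapfree_alignment_columns_equal_positions(self, rng):
        seq = random_seq(rng, 25)
        msa = {"A": seq, "B": seq}
        profs = [profile("A", range(11)), profile("B", range(11))]
        aligned = map_profiles_to_msa(profs, msa, toxin_sequences={"A": seq, "B": seq})
        for acc in ("A", "B"):
            row = aligned.column_scores.loc[acc]
            assert list(row[range(1, 12)]) == list(range(11))
            # the last 14 residues carry no score: no 15-mer starts there
            assert row[range(12, 26)].isna().all()

    def test_gap_shifts_scores_right(self, rng):
        seq_a = random_seq(rng, 22)
        seq_b = random_seq(rng, 19)
        msa = {"A": seq_a, "B": "---" + seq_b}
        profs = [profile("A", range(8)), profile("B", [5.0] * 5)]
        aligned = map_profiles_to_msa(profs, msa)
        row_b = aligned.column_scores.loc["B"]
        assert row_b[range(1, 4)].isna().all()  # gap columns carry no value
        # hand-constructed oracle: B's score for position i lands on column i+3
        assert list(row_b[range(4, 9)]) == [5.0] * 5

    def test_mismatched_row_rejected_by_accession(self):
        msa = {"A": "ACDEFGHIKLMNPQRST"}
        with pytest.raises(ValueError, match="A"):
            map_profiles_to_msa(
                [profile("A", [1.0, 2.0, 3.0])],
                msa,
                toxin_sequences={"A": "ACDEFGHIKLMNPQRSV"},
            )

    def test_missing_accession_rejected(self):
        with pytest.raises(KeyError, match="B"):
            map_profiles_to_msa([profile("B", [1.0])], {"A": "ACDEFGHIKLMNPQR"})


def shared_block_fixture(rng, n_hot, n_cold=5, length=40, lo=10, hi=14):
    """Equal-length toxins; `n_hot` of them elevated on windows lo..hi."""
    msa = {}
    profs = []
    for i in range(n_hot + n_cold):
        acc = f"T{i:02d}"
        msa[acc] = random_seq(rng, length)
        scores = np.zeros(length - 14)
        if i < n_hot:
            scores[lo - 1 : hi] = 100.0
        profs.append(profile(acc, scores))
    return msa, profs


class TestSharedSegments:
    def test_no_scores_above_threshold_gives_empty_list(self, rng):
        msa, profs = shared_block_fixture(rng, n_hot=0)
        aligned = map_profiles_to_msa(profs, msa)
        assert find_shared_segments(aligned, threshold=50.0) == []

    def test_twelve_sharing_toxins_give_one_segment(self, rng):
        msa, profs = shared_block_fixture(rng, n_hot=12, lo=10, hi=14)
        aligned = map_profiles_to_msa(profs, msa)
        segments = find_shared_segments(aligned, threshold=50.0, min_share=10)
        assert len(segments) == 1
        seg = segments[0]
        assert (seg.start_col, seg.end_col) == (10, 14)
        assert len(seg.member_toxins) == 12

    def test_nine_toxins_below_min_share_boundary(self, rng):
        msa, profs = shared_block_fixture(rng, n_hot=9)
        aligned = map_profiles_to_msa(profs, msa)
        assert find_shared_segments(aligned, threshold=50.0, min_share=10) == []

    def test_infinite_threshold_rejected(self, rng):
        msa, profs = shared_block_fixture(rng, n_hot=3)
        aligned = map_profiles_to_msa(profs, msa)
        with pytest.raises(ValueError):
            find_shared_segments(aligned, threshold=float("inf"))


class TestCoreMotif:
    def run_fixture(self, rng, run_length, length=60):
        """One clearly top toxin with a significant run of given length."""
        msa, profs = {}, []
        n_windows = length - 14
        start = 10
        sequences = {}
        for i in range(12):
            acc = f"T{i:02d}"
            seq = random_seq(rng, length)
            msa[acc] = seq
            sequences[acc] = seq
            scores = np.zeros(n_windows)
            peak = 200.0 if i == 0 else 100.0
            scores[start - 1 : start - 1 + run_length] = peak
            profs.append(profile(acc, scores))
        aligned = map_profiles_to_msa(profs, msa)
        (segment,) = find_shared_segments(aligned, threshold=50.0, min_share=10)
        core = extract_core_motif(
            segment, aligned, profs, threshold=50.0, toxin_sequences=sequences
        )
        return core, sequences, start

    @pytest.mark.parametrize("run_length, core_length", [(1, 15), (8, 8), (13, 3)])
    def test_core_length_law(self, rng, run_length, core_length):
        """|core| = 15 - run + 1 (a 13-peptide run shares 3 residues)."""
        core, sequences, start = self.run_fixture(rng, run_length)
        assert core.run_length == run_length
        assert len(core.core) == core_length == 15 - run_length + 1
        expected = sequences[core.top_accession][
            start + run_length - 2 : start + 14
        ]
        assert core.core == expected

    def test_top_toxin_is_highest_peak(self, rng):
        core, _, _ = self.run_fixture(rng, 5)
        assert core.top_accession == "T00"


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


class TestCollectSimilar:
    def build(self, rng, n_toxins=3, length=45, core_cols=(16, 23)):
        msa, profs, sequences = {}, [], {}
        for i in range(n_toxins):
            acc = f"T{i:02d}"
            seq = random_seq(rng, length)
            msa[acc] = seq
            sequences[acc] = seq
            profs.append(profile(acc, rng.normal(size=length - 14)))
        return msa, profs, sequences

    def oracle_sums(self, core_str, a, b, sequences, profs, max_mismatch):
        """Exhaustive scan over all 15-mers and Hamming comparisons."""
        sums = {}
        for prof in profs:
            seq = sequences[prof.accession]
            segment = seq[a - 1 : b]
            if hamming(segment, core_str) > max_mismatch:
                continue
            total = 0.0
            for t in range(1, len(seq) - 14 + 1):
                if t <= a and t + 14 >= b:
                    total += prof.scores[t - 1]
            sums[prof.accession] = total
        return sums

    def test_identical_toxin_gets_identical_sum(self, rng):
        msa, profs, sequences = self.build(rng, n_toxins=1)
        # clone the single toxin under a new accession
        seq = sequences["T00"]
        msa["C"] = seq
        sequences["C"] = seq
        profs.append(SignalProfile("C", profs[0].scores.copy(), raw=profs[0].raw))
        aligned = map_profiles_to_msa(profs, msa)
        seg_scores = np.zeros_like(profs[0].scores)
        seg_scores[4:12] = 100.0
        hot = [
            SignalProfile("T00", seg_scores, raw=seg_scores),
            SignalProfile("C", seg_scores, raw=seg_scores),
        ]
        (segment,) = find_shared_segments(
            map_profiles_to_msa(hot, msa), threshold=50.0, min_share=2
        )
        core = extract_core_motif(
            segment, aligned, hot, threshold=50.0, toxin_sequences=sequences
        )
        sums = collect_similar(core, aligned, profs, sequences)
        assert sums["T00"] == pytest.approx(sums["C"])

    def test_four_mismatches_excluded_three_included(self, rng):
        from epimap.epitopes import CoreMotif

        msa, profs, sequences = self.build(rng, n_toxins=2)
        a, b = 16, 23
        core_str = sequences["T00"][a - 1 : b]
        # rewrite T01 to carry the core with a controlled number of mismatches
        for n_mm, expect_in in [(3, True), (4, False)]:
            seq = list(sequences["T01"])
            seq[a - 1 : b] = list(core_str)
            alternatives = [r for r in STANDARD_RESIDUES]
            for j in range(n_mm):
                pos = a - 1 + j
                seq[pos] = next(r for r in alternatives if r != core_str[j])
            mutated = "".join(seq)
            msa2 = {"T00": sequences["T00"], "T01": mutated}
            seqs2 = dict(msa2)
            profs2 = [profs[0], profile("T01", profs[1].scores)]
            aligned = map_profiles_to_msa(profs2, msa2)
            core = CoreMotif(
                core=core_str,
                columns=tuple(range(a, b + 1)),
                top_accession="T00",
                run_start=9,
                run_length=8,
            )
            sums = collect_similar(core, aligned, profs2, seqs2, max_mismatch=3)
            assert ("T01" in sums) == expect_in

    def test_matches_exhaustive_oracle_on_random_fixtures(self, rng):
        from epimap.epitopes import CoreMotif

        for _ in range(50):
            msa, profs, sequences = self.build(
                rng, n_toxins=int(rng.integers(2, 6))
            )
            a = int(rng.integers(5, 20))
            b = a + int(rng.integers(4, 10))
            core_str = sequences["T00"][a - 1 : b]
            core = CoreMotif(
                core=core_str,
                columns=tuple(range(a, b + 1)),
                top_accession="T00",
                run_start=1,
                run_length=15 - (b - a),
            )
            aligned = map_profiles_to_msa(profs, msa)
            mm = int(rng.integers(0, 5))
            sums = collect_similar(core, aligned, profs, sequences, max_mismatch=mm)
            oracle = self.oracle_sums(core_str, a, b, sequences, profs, mm)
            assert sums.keys() == oracle.keys()
            for acc in sums:
                assert sums[acc] == pytest.approx(oracle[acc])

    def test_zero_mismatch_reduces_to_exact_containment(self, rng):
        from epimap.epitopes import CoreMotif

        msa, profs, sequences = self.build(rng, n_toxins=4)
        a, b = 10, 17
        core_str = sequences["T00"][a - 1 : b]
        core = CoreMotif(
            core=core_str, columns=tuple(range(a, b + 1)),
            top_accession="T00", run_start=1, run_length=8,
        )
        aligned = map_profiles_to_msa(profs, msa)
        sums = collect_similar(core, aligned, profs, sequences, max_mismatch=0)
        for acc in sums:
            assert sequences[acc][a - 1 : b] == core_str
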