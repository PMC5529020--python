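"""Library design: sanitization, tiling, deduplication and layout."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epimap import (
    assign_layout,
    build_library,
    sanitize_sequence,
    tile_sequence,
)
from epimap.library import STANDARD_RESIDUES

from conftest import make_toxin

residue = st.sampled_from(STANDARD_RESIDUES)
protein = st.text(alphabet=residue, min_size=1, max_size=60)


class TestSanitize:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("ACDX", "ACDG"),
            ("ACDEF", "ACDEF"),
            ("XXX", "GGG"),
            ("ABZJUOX", "AGGGGGG"),
            ("acd", "ACD"),
        ],
    )
    def test_ambiguity_codes_become_glycine(self, raw, expected):
        assert sanitize_sequence(raw) == expected

    def test_non_letter_rejected_with_position(self):
        with pytest.raises(ValueError, match="position 3"):
            sanitize_sequence("AC*DE")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sanitize_sequence("")

    @given(protein)
    @settings(max_examples=50, derandomize=True)
    def test_length_preserved_and_standard(self, seq):
        out = sanitize_sequence(seq)
        assert len(out) == len(seq)
        assert set(out) <= set(STANDARD_RESIDUES)


class TestTiling:
    @pytest.mark.parametrize("length, n_tiles", [(20, 6), (15, 1), (14, 0), (29, 15)])
    def test_tile_count(self, length, n_tiles):
        toxin = make_toxin("T1", ("ACDEFGHIKLMNPQRSTVWY" * 3)[:length])
        assert len(tile_sequence(toxin)) == n_tiles

    def test_length_15_tile_equals_sequence(self):
        seq = "ACDEFGHIKLMNPQR"
        tiles = tile_sequence(make_toxin("T1", seq))
        assert len(tiles) == 1
        assert tiles[0].peptide == seq
        assert tiles[0].origins == {("T1", 1)}

    @given(protein)
    @settings(max_examples=100, derandomize=True)
    def test_tiling_law_and_coverage(self, seq):
        """Every window 1..L-14 is covered exactly once, N->C order."""
        toxin = make_toxin("T1", seq)
        tiles = tile_sequence(toxin)
        assert len(tiles) == max(len(seq) - 14, 0)
        for i, tile in enumerate(tiles, start=1):
            assert tile.peptide == seq[i - 1 : i + 14]  # substring oracle
            assert tile.origins == {("T1", i)}


class TestBuildLibrary:
    def test_identical_sequences_deduplicate(self):
        seq = "ACDEFGHIKLMNPQR"
        lib = build_library([make_toxin("A", seq), make_toxin("B", seq)])
        assert len(lib) == 1
        assert lib.tiles[seq].origins == {("A", 1), ("B", 1)}

    def test_no_collisions_across_toxins(self):
        # all windows distinct within and between the two sequences
        lib = build_library(
            [
                make_toxin("A", "ACDEFGHIKLMNPQRSTVWY"),  # 20 -> 6 tiles
                make_toxin("B", "YWVTSRQPNMLKIHGF"),  # 16 -> 2 tiles
            ]
        )
        assert len(lib) == 8  # 6 + 2

    def test_internal_repeat_collapses(self):
        # a 16-mer of one letter repeats its 15-mer window internally
        lib = build_library([make_toxin("A", "A" * 16)])
        assert len(lib) == 1
        assert lib.tiles["A" * 15].origins == {("A", 1), ("A", 2)}

    def test_duplicate_accession_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_library([make_toxin("A", "A" * 20), make_toxin("A", "C" * 20)])

    @given(st.lists(protein.filter(lambda s: len(s) >= 15), min_size=1, max_size=6))
    @settings(max_examples=50, derandomize=True)
    def test_dedup_conserves_window_count(self, seqs):
        toxins = [make_toxin(f"T{i}", s) for i, s in enumerate(seqs)]
        lib = build_library(toxins)
        total_windows = sum(max(len(s) - 14, 0) for s in seqs)
        assert lib.total_origins == total_windows


class TestLayout:
    @pytest.fixture
    def library(self):
        return build_library(
            [make_toxin("A", "ACDEFGHIKLMNPQRST")]  # 3 unique 15-mers
        )

    def test_field_count(self, library):
        layout = assign_layout(library, replicates=5, corner_field_count=4, seed=1)
        assert len(layout) == 3 * 5 + 4

    def test_same_seed_identical(self, library):
        a = assign_layout(library, seed=7, corner_field_count=10)
        b = assign_layout(library, seed=7, corner_field_count=10)
        assert a.fields == b.fields

    def test_different_seed_differs(self, library):
        a = assign_layout(library, seed=7, corner_field_count=852)
        b = assign_layout(library, seed=8, corner_field_count=852)
        assert a.fields != b.fields

    def test_replicate_multiset_under_many_seeds(self, library):
        """Each peptide occupies exactly `replicates` fields for any seed."""
        for seed in range(100):
            layout = assign_layout(
                library, replicates=5, corner_field_count=6, seed=seed
            )
            counts = {}
            for fid, pep, corner in layout.fields:
                counts[(pep, corner)] = counts.get((pep, corner), 0) + 1
            for pep in library.peptides:
                assert counts[(pep, False)] == 5
            assert counts[(layout.corner_peptide, True)] == 6

    def test_layout_is_bijection(self, library):
        layout = assign_layout(library, corner_field_count=5, seed=3)
        ids = [fid for fid, _, _ in layout.fields]
        assert sorted(ids) == list(range(len(layout)))
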