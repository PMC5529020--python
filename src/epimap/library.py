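"""Peptide library design: tiling, deduplication and randomized array layout.

A toxin set is turned into a library of overlapping 15-mer peptides (window
step 1, i.e. 14-residue overlap between neighbours), deduplicated across the
whole set, and assigned to randomized replicate fields on a virtual
microarray together with a population of sticky corner-control fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity / non-standard one-letter codes replaced by glycine.
AMBIGUOUS_RESIDUES = frozenset("XBZJUO")
#: Lysine/arginine-rich control peptide highly prone to unspecific binding.
CORNER_PEPTIDE = "KKKRKKKRKKKRKKK"

DEFAULT_K = 15
DEFAULT_REPLICATES = 5
DEFAULT_CORNER_FIELDS = 852


@dataclass(frozen=True)
class ToxinRecord:
    """One venom-protein sequence with its identity metadata.

    Parameters
    ----------
    accession : str
        Unique identifier (UniProt-style) within a dataset.
    species : str
        Source snake species.
    family : str
        Protein family, e.g. ``SVMP``, ``PLA2``, ``SVSP``.
    subgroup : str or None
        Optional finer classification (e.g. ``acidic D49``, ``basic K49``).
    is_partial : bool
        Whether the sequence is an incomplete fragment.
    sequence : str
        Amino-acid sequence over the 20 standard letters (after
        :func:`sanitize_sequence`).
    """

    accession: str
    species: str = ""
    family: str = ""
    subgroup: str | None = None
    is_partial: bool = False
    sequence: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - set(STANDARD_RESIDUES)
        if bad:
            raise ValueError(
                f"{self.accession}: non-standard residues {sorted(bad)}; "
                "run sanitize_sequence first"
            )


@dataclass
class PeptideTile:
    """A unique peptide string with every (accession, start) that produces it.

    ``start`` is the 1-based position of the peptide's N-terminal residue in
    the parent sequence.
    """

    peptide: str
    origins: set[tuple[str, int]] = field(default_factory=set)


@dataclass
class PeptideLibrary:
    """Deduplicated peptide tiles keyed by peptide string (insertion order)."""

    tiles: dict[str, PeptideTile]
    k: int = DEFAULT_K
    overlap: int = DEFAULT_K - 1

    @property
    def peptides(self) -> list[str]:
        return list(self.tiles)

    def __len__(self) -> int:
        return len(self.tiles)

    @property
    def total_origins(self) -> int:
        """Total tiling-window count before deduplication."""
        return sum(len(t.origins) for t in self.tiles.values())


@dataclass
class ArrayLayout:
    """Randomized assignment of peptides and corner controls to array fields.

    ``fields`` is a flat list of ``(field_id, peptide, is_corner_control)``;
    grid geometry is abstracted away because the analysis never uses 2-D
    coordinates.
    """

    fields: list[tuple[int, str, bool]]
    replicates: int = DEFAULT_REPLICATES
    corner_peptide: str = CORNER_PEPTIDE
    corner_field_count: int = DEFAULT_CORNER_FIELDS
    rng_seed: int = 0

    def __len__(self) -> int:
        return len(self.fields)


def sanitize_sequence(raw: str) -> str:
    """Replace ambiguity codes (X, B, Z, J, U, O) with glycine.

    Standard residues pass through unchanged and length is preserved.
    Non-letter characters are rejected with the offending 1-based position.
    """
    out = []
    for pos, ch in enumerate(raw, start=1):
        if not ch.isalpha():
            raise ValueError(f"non-letter character {ch!r} at position {pos}")
        ch = ch.upper()
        out.append("G" if ch in AMBIGUOUS_RESIDUES else ch)
    if not out:
        raise ValueError("empty sequence")
    return "".join(out)


def tile_sequence(toxin: ToxinRecord, k: int = DEFAULT_K) -> list[PeptideTile]:
    """Tile a sanitized sequence into overlapping k-mers (step 1), N→C order.

    A sequence of length ``L`` yields ``max(L - k + 1, 0)`` tiles; tile ``i``
    (1-based) starts at residue ``i``. Sequences shorter than ``k`` yield an
    empty list.
    """
    seq = toxin.sequence
    return [
        PeptideTile(seq[i : i + k], {(toxin.accession, i + 1)})
        for i in range(len(seq) - k + 1)
    ]


def build_library(toxins: list[ToxinRecord], k: int = DEFAULT_K) -> PeptideLibrary:
    """Deduplicate tiles across a toxin set into a :class:`PeptideLibrary`.

    One tile is kept per distinct peptide string; its origins are the union
    of every (accession, start) producing that string. Deterministic given
    input order. Duplicate accessions are rejected.
    """
    accs = [t.accession for t in toxins]
    if len(accs) != len(set(accs)):
        dupes = sorted({a for a in accs if accs.count(a) > 1})
        raise ValueError(f"duplicate accessions: {dupes}")
    tiles: dict[str, PeptideTile] = {}
    for toxin in toxins:
        for tile in tile_sequence(toxin, k=k):
            if tile.peptide in tiles:
                tiles[tile.peptide].origins |= tile.origins
            else:
                tiles[tile.peptide] = tile
    return PeptideLibrary(tiles, k=k, overlap=k - 1)


def assign_layout(
    library: PeptideLibrary,
    replicates: int = DEFAULT_REPLICATES,
    corner_field_count: int = DEFAULT_CORNER_FIELDS,
    seed: int = 0,
    corner_peptide: str = CORNER_PEPTIDE,
) -> ArrayLayout:
    """Assign each library peptide to `replicates` random fields plus corners.

    The assignment is a seeded random permutation of all field contents, so
    the same seed reproduces the identical layout. Field ids run 0..n-1.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    contents: list[tuple[str, bool]] = [
        (pep, False) for pep in library.peptides for _ in range(replicates)
    ]
    contents += [(corner_peptide, True)] * corner_field_count
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(contents))
    fields = [
        (fid, contents[j][0], contents[j][1]) for fid, j in enumerate(order)
    ]
    return ArrayLayout(
        fields,
        replicates=replicates,
        corner_peptide=corner_peptide,
        corner_field_count=corner_field_count,
        rng_seed=seed,
    )
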