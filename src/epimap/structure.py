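"""Painting per-residue recognition scores onto PDB structures.

Each residue covered by a recognized core motif receives that peptide
series' sum of running-median scores (overlapping cores resolve to the
per-residue maximum). The scores are linearly rescaled to [0, 99.99] and
written into the temperature-factor column (fixed-width columns 61-66, two
decimals) of every atom of the residue — the conventional carrier for score
painting — while every other byte of the file is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .epitopes import CoreMotif


@dataclass
class ResidueScoreMap:
    """Per-residue summed recognition scores for one toxin."""

    accession: str
    chain: str | None = None
    scores: dict[int, float] = field(default_factory=dict)  # 1-based position

    def max_score(self) -> float:
        return max(self.scores.values(), default=0.0)


def residue_scores(
    core_motifs: list[CoreMotif], accession: str, chain: str | None = None
) -> ResidueScoreMap:
    """Per-residue score map for one toxin from its recognized core motifs.

    Every residue inside a core's matched span carries that series' sum;
    residues in no core stay at 0; overlaps take the maximum.
    """
    out = ResidueScoreMap(accession=accession, chain=chain)
    for core in core_motifs:
        if accession not in core.per_toxin_sum:
            continue
        total = core.per_toxin_sum[accession]
        a, b = core.per_toxin_span[accession]
        for pos in range(a, b + 1):
            out.scores[pos] = max(out.scores.get(pos, 0.0), total)
    return out


def write_scored_structure(
    pdb_in: str | Path,
    score_map: ResidueScoreMap,
    pdb_out: str | Path,
    offset: int = 0,
    chain: str | None = None,
    scale_max: float = 99.99,
) -> int:
    """Write rescaled residue scores into the B-factor column of a PDB file.

    ``offset`` maps structure residue numbering to toxin positions
    (toxin position = residue number - offset). Atoms of residues with no
    score (or outside ``chain``, if given) are set to 0.00. Returns the
    number of atom records painted with a non-zero score. Raises on
    malformed ATOM/HETATM records.
    """
    pdb_in, pdb_out = Path(pdb_in), Path(pdb_out)
    top = score_map.max_score()
    scale = (scale_max / top) if top > 0 else 0.0
    painted = 0
    out_lines: list[str] = []
    for lineno, line in enumerate(pdb_in.read_text().splitlines(keepends=True), 1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line.rstrip("\n")) < 66:
                raise ValueError(
                    f"malformed atom record at line {lineno}: too short"
                )
            try:
                resseq = int(line[22:26])
            except ValueError as exc:
                raise ValueError(
                    f"malformed residue number at line {lineno}"
                ) from exc
            rec_chain = line[21]
            value = 0.0
            if chain is None or rec_chain == chain:
                value = score_map.scores.get(resseq - offset, 0.0) * scale
            if value > 0:
                painted += 1
            line = f"{line[:60]}{value:6.2f}{line[66:]}"
        out_lines.append(line)
    pdb_out.write_text("".join(out_lines))
    return painted


def read_bfactors(pdb_path: str | Path, chain: str | None = None) -> dict[int, float]:
    """Read per-residue B-factors back (first atom of each residue)."""
    out: dict[int, float] = {}
    for line in Path(pdb_path).read_text().splitlines():
        if line.startswith(("ATOM  ", "HETATM")):
            if chain is not None and line[21] != chain:
                continue
            resseq = int(line[22:26])
            out.setdefault(resseq, float(line[60:66]))
    return out
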