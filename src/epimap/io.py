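"""Readers and writers for the pipeline's plain-text formats.

Sequences travel as FASTA (Biopython), toxin metadata as a tab-separated
sidecar (accession, species, family, subgroup, is_partial), alignments as
aligned FASTA or Clustal (Biopython AlignIO), and every tabular
intermediate as a TSV with a header line.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .library import ArrayLayout, PeptideLibrary, ToxinRecord, sanitize_sequence

META_COLUMNS = ["accession", "species", "family", "subgroup", "is_partial"]


def read_toxins(fasta: str | Path, metadata: str | Path | None = None) -> list[ToxinRecord]:
    """Read toxins from FASTA (+ optional metadata sidecar), sanitizing."""
    meta = {}
    if metadata is not None:
        table = pd.read_csv(metadata, sep="\t", dtype=str).fillna("")
        for _, row in table.iterrows():
            meta[row["accession"]] = row
    records = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        row = meta.get(rec.id)
        records.append(
            ToxinRecord(
                accession=rec.id,
                species=row["species"] if row is not None else "",
                family=row["family"] if row is not None else "",
                subgroup=(row["subgroup"] or None) if row is not None else None,
                is_partial=(
                    row["is_partial"].lower() in ("1", "true", "yes")
                    if row is not None
                    else False
                ),
                sequence=sanitize_sequence(str(rec.seq)),
            )
        )
    return records


def write_toxins(
    toxins: list[ToxinRecord], fasta: str | Path, metadata: str | Path | None = None
) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.accession, description="") for t in toxins
    ]
    SeqIO.write(records, str(fasta), "fasta")
    if metadata is not None:
        pd.DataFrame(
            [
                {
                    "accession": t.accession,
                    "species": t.species,
                    "family": t.family,
                    "subgroup": t.subgroup or "",
                    "is_partial": str(t.is_partial).lower(),
                }
                for t in toxins
            ],
            columns=META_COLUMNS,
        ).to_csv(metadata, sep="\t", index=False)


def read_msa(path: str | Path, fmt: str | None = None) -> dict[str, str]:
    """Read an MSA (aligned FASTA or Clustal) as accession -> aligned row."""
    path = Path(path)
    if fmt is None:
        fmt = "clustal" if path.suffix.lower() in (".aln", ".clustal") else "fasta"
    alignment = AlignIO.read(str(path), fmt)
    return {rec.id: str(rec.seq).upper() for rec in alignment}


def write_library(library: PeptideLibrary, path: str | Path) -> None:
    rows = [
        {
            "peptide": tile.peptide,
            "origins": ";".join(
                f"{acc}:{start}" for acc, start in sorted(tile.origins)
            ),
        }
        for tile in library.tiles.values()
    ]
    pd.DataFrame(rows, columns=["peptide", "origins"]).to_csv(
        path, sep="\t", index=False
    )


def write_layout(layout: ArrayLayout, path: str | Path) -> None:
    pd.DataFrame(
        layout.fields, columns=["field_id", "peptide", "is_corner_control"]
    ).to_csv(path, sep="\t", index=False)


def read_layout(path: str | Path) -> ArrayLayout:
    table = pd.read_csv(path, sep="\t")
    fields = [
        (int(r.field_id), str(r.peptide), bool(r.is_corner_control))
        for r in table.itertuples()
    ]
    corner = sum(1 for f in fields if f[2])
    return ArrayLayout(fields, corner_field_count=corner)


def read_intensities(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    expected = {"field_id", "peptide", "intensity"}
    if not expected <= set(table.columns):
        raise ValueError(f"intensity table must have columns {sorted(expected)}")
    return table


def write_intensities(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.4f")
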