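"""MSA-anchored epitope segments, core motifs and mismatch-tolerant sums.

Per-toxin running-median profiles are anchored to a subfamily multiple
sequence alignment by placing the score of the 15-mer starting at ungapped
position i on the alignment column of residue i (gap columns carry no
value). Maximal column intervals in which at least ``min_share`` toxins show
an above-threshold score become epitope segments. For each segment, the
top-scoring toxin's maximal run of consecutive significant 15-mers defines
the core motif — the residue window shared by every 15-mer of the run, of
length ``15 - run + 1``. Finally, each toxin whose residues at the core's
alignment columns lie within a Hamming distance of ``max_mismatch`` of the
core contributes the sum of running-median scores of all its 15-mers
containing that window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signalproc import SignalProfile


@dataclass
class AlignedProfile:
    """Per-toxin scores laid out on alignment columns (NaN where absent)."""

    msa: dict[str, str]
    column_scores: pd.DataFrame  # rows: accession; columns: 1..n_columns

    @property
    def accessions(self) -> list[str]:
        return list(self.column_scores.index)

    @property
    def n_columns(self) -> int:
        return self.column_scores.shape[1]


@dataclass
class EpitopeSegment:
    """A maximal alignment-column interval recognized across toxins."""

    start_col: int  # 1-based inclusive
    end_col: int
    member_toxins: list[str]
    peak_scores: dict[str, float]


@dataclass
class CoreMotif:
    """Core residues of a recognized peptide series and per-toxin sums.

    ``core`` is the window shared by all 15-mers of the top toxin's maximal
    significant run; ``columns`` are its alignment columns; ``per_toxin_sum``
    maps each similar toxin to its sum of running-median scores;
    ``per_toxin_span`` to the (start, end) 1-based residue positions of the
    matched window in that toxin's own sequence.
    """

    core: str
    columns: tuple[int, ...]
    top_accession: str
    run_start: int  # profile position of the first 15-mer of the run
    run_length: int
    max_mismatch: int = 3
    per_toxin_sum: dict[str, float] = field(default_factory=dict)
    per_toxin_span: dict[str, tuple[int, int]] = field(default_factory=dict)


def _column_of_residue(aligned_row: str, gap: str = "-") -> np.ndarray:
    """1-based alignment column of each ungapped residue, in sequence order."""
    return np.array(
        [c + 1 for c, ch in enumerate(aligned_row) if ch != gap], dtype=int
    )


def map_profiles_to_msa(
    profiles: list[SignalProfile],
    msa: dict[str, str],
    gap: str = "-",
    toxin_sequences: dict[str, str] | None = None,
) -> AlignedProfile:
    """Anchor score profiles to alignment columns via N-terminal positions.

    Every profile accession must be present in the MSA; if
    ``toxin_sequences`` is given, each row is checked to ungap to the toxin
    sequence. The last 14 residues of every toxin carry no score (no 15-mer
    starts there).
    """
    n_col = max((len(r) for r in msa.values()), default=0)
    rows = {}
    for prof in profiles:
        if prof.accession not in msa:
            raise KeyError(f"accession {prof.accession!r} missing from MSA")
        row = msa[prof.accession]
        cols = _column_of_residue(row, gap=gap)
        if toxin_sequences is not None:
            ungapped = row.replace(gap, "")
            if ungapped != toxin_sequences[prof.accession]:
                raise ValueError(
                    f"alignment row for {prof.accession!r} does not ungap "
                    "to the toxin sequence"
                )
        values = np.full(n_col, np.nan)
        for i, score in enumerate(prof.scores):  # i = position - 1
            values[cols[i] - 1] = score
        rows[prof.accession] = values
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = np.arange(1, n_col + 1)
    return AlignedProfile(msa=dict(msa), column_scores=frame)


def find_shared_segments(
    aligned: AlignedProfile, threshold: float, min_share: int = 10
) -> list[EpitopeSegment]:
    """Maximal runs of columns with any above-threshold score, shared widely.

    Consecutive qualifying columns (>= 1 toxin at or above threshold) are
    merged into intervals; an interval is reported iff at least ``min_share``
    toxins have an above-threshold score somewhere inside it. Segments are
    disjoint and ordered by column.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    hot = aligned.column_scores.to_numpy() >= threshold  # NaN compares False
    any_hot = hot.any(axis=0)
    segments: list[EpitopeSegment] = []
    c = 0
    n = len(any_hot)
    while c < n:
        if not any_hot[c]:
            c += 1
            continue
        start = c
        while c < n and any_hot[c]:
            c += 1
        end = c - 1
        inside = hot[:, start : end + 1].any(axis=1)
        members = [aligned.accessions[i] for i in np.nonzero(inside)[0]]
        if len(members) >= min_share:
            block = aligned.column_scores.iloc[
                np.nonzero(inside)[0], start : end + 1
            ]
            peaks = block.max(axis=1, skipna=True).to_dict()
            segments.append(
                EpitopeSegment(
                    start_col=start + 1,
                    end_col=end + 1,
                    member_toxins=members,
                    peak_scores={a: float(v) for a, v in peaks.items()},
                )
            )
    return segments


def extract_core_motif(
    segment: EpitopeSegment,
    aligned: AlignedProfile,
    profiles: list[SignalProfile],
    threshold: float,
    toxin_sequences: dict[str, str],
    k: int = 15,
    gap: str = "-",
) -> CoreMotif:
    """Core motif from the top-scoring member's maximal significant run.

    The member with the highest peak (ties broken by accession order) is
    scanned for maximal runs of consecutive significant 15-mers whose score
    columns overlap the segment; the longest such run (first on ties) gives
    the core: the residues common to all 15-mers of the run, i.e. positions
    ``run_start + run - 1 .. run_start + 14`` of the toxin, of length
    ``15 - run + 1``. Runs longer than 15 share no residues and are rejected.
    """
    if not segment.member_toxins:
        raise ValueError("empty segment")
    top = min(
        segment.member_toxins, key=lambda a: (-segment.peak_scores[a], a)
    )
    prof = next(p for p in profiles if p.accession == top)
    seq = toxin_sequences[top]
    cols = _column_of_residue(aligned.msa[top], gap=gap)
    sig = prof.scores >= threshold
    # maximal runs of significant 15-mers overlapping the segment columns
    best: tuple[int, int] | None = None  # (start index 0-based, length)
    i = 0
    while i < len(sig):
        if not sig[i]:
            i += 1
            continue
        j = i
        while j < len(sig) and sig[j]:
            j += 1
        run_cols = cols[i:j]
        if np.any(
            (run_cols >= segment.start_col) & (run_cols <= segment.end_col)
        ):
            if best is None or (j - i) > best[1]:
                best = (i, j - i)
        i = j
    if best is None:
        raise ValueError(
            f"top toxin {top!r} has no significant run overlapping the segment"
        )
    start0, run = best
    if run > k:
        raise ValueError("significant run longer than the peptide length")
    core_start = start0 + run - 1  # 0-based residue index of core start
    core_end = start0 + k - 1  # inclusive
    core = seq[core_start : core_end + 1]
    columns = tuple(int(c) for c in cols[core_start : core_end + 1])
    return CoreMotif(
        core=core,
        columns=columns,
        top_accession=top,
        run_start=start0 + 1,
        run_length=run,
    )


def collect_similar(
    core: CoreMotif,
    aligned: AlignedProfile,
    profiles: list[SignalProfile],
    toxin_sequences: dict[str, str],
    max_mismatch: int = 3,
    k: int = 15,
    gap: str = "-",
) -> dict[str, float]:
    """Sum running-median scores of 15-mers matching the core per toxin.

    For each toxin, the residues at the core's alignment columns (gaps count
    as mismatches) are compared to the core; toxins within Hamming distance
    ``max_mismatch`` contribute the sum of the running-median scores of all
    their 15-mers containing the matched window. Fills and returns
    ``core.per_toxin_sum`` (and records the matched residue spans).
    """
    core.max_mismatch = max_mismatch
    core.per_toxin_sum = {}
    core.per_toxin_span = {}
    prof_by_acc = {p.accession: p for p in profiles}
    for acc, row in aligned.msa.items():
        if acc not in prof_by_acc:
            continue
        seq = toxin_sequences[acc]
        cols = _column_of_residue(row, gap=gap)
        col_to_pos = {int(c): i + 1 for i, c in enumerate(cols)}
        residues = []
        positions = []
        for c in core.columns:
            pos = col_to_pos.get(c)
            if pos is None:
                residues.append(gap)
            else:
                residues.append(seq[pos - 1])
                positions.append(pos)
        if not positions:
            continue
        mismatches = sum(a != b for a, b in zip(residues, core.core))
        if mismatches > max_mismatch:
            continue
        a, b = min(positions), max(positions)
        if b - a + 1 > k:
            continue  # window torn apart by insertions
        prof = prof_by_acc[acc]
        lo = max(1, b - k + 1)
        hi = min(a, len(prof))
        if lo > hi:
            continue
        total = float(np.sum(prof.scores[lo - 1 : hi]))
        core.per_toxin_sum[acc] = total
        core.per_toxin_span[acc] = (a, b)
    return core.per_toxin_sum
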