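"""Sequence-logo matrices and rank-based residue-binding association scores.

Two per-position views of a set of equal-length core sequences:

* a Shannon logo matrix — per-position residue frequencies (gaps excluded),
  information content ``log2(20) - H`` in bits, and letter heights
  ``frequency * information``;
* a residue-association matrix — for every (position, residue) pair present
  in some but not all sequences, a Wilcoxon rank-sum Z-score linking the
  residue's presence to the per-toxin sum-of-scores ranking (positive Z:
  association with high binding). Gaps are kept as a 21st category here,
  since a gap can associate with low binding. Two-sided normal p-values are
  corrected with Benjamini-Hochberg across all defined pairs.

This is a re-implementation of the rank-based genotype-phenotype association
approach popularized by the SigniSite server, with the multiple-testing
family (all defined position-residue pairs) and BH correction chosen here.
Fully conserved residues carry no Z-score: they rank neither high nor low.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .significance import bh_call

N_RESIDUE_TYPES = 20
MAX_BITS = np.log2(N_RESIDUE_TYPES)
GAP = "-"


@dataclass
class LogoMatrix:
    """Per-position residue frequencies, information (bits) and heights."""

    frequencies: pd.DataFrame  # rows: 1-based position; columns: residues
    information: pd.Series  # bits per position, in [0, log2(20)]
    heights: pd.DataFrame  # frequency * information


@dataclass
class ResidueAssociationMatrix:
    """Rank-sum Z-scores per (position, residue) and their significance."""

    z: pd.DataFrame  # NaN where undefined (residue absent or conserved)
    counts: pd.DataFrame  # carriers per (position, residue)
    pvalues: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    corrected: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    mask: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    degenerate: bool = False  # constant sums: every Z undefined


def _check_equal_length(sequences: list[str]) -> int:
    if not sequences:
        raise ValueError("at least one sequence is required")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences must have equal length")
    return length


def logo_matrix(sequences: list[str]) -> LogoMatrix:
    """Shannon logo matrix of equal-length sequences (gaps excluded)."""
    length = _check_equal_length(sequences)
    residues = sorted({ch for s in sequences for ch in s if ch != GAP})
    freq = pd.DataFrame(
        0.0, index=np.arange(1, length + 1), columns=residues
    )
    info = pd.Series(0.0, index=freq.index)
    for pos in range(length):
        col = [s[pos] for s in sequences if s[pos] != GAP]
        if not col:
            continue
        counts = pd.Series(col).value_counts()
        p = counts / counts.sum()
        freq.loc[pos + 1, p.index] = p
        entropy = float(-(p * np.log2(p)).sum())
        info[pos + 1] = MAX_BITS - entropy
    heights = freq.mul(info, axis=0)
    return LogoMatrix(frequencies=freq, information=info, heights=heights)


def residue_zscores(
    sequences: list[str], sums: dict[str, float] | list[float]
) -> ResidueAssociationMatrix:
    """Wilcoxon rank-sum Z for each (position, residue) vs. the score ranking.

    ``sums`` gives one sum-of-scores per sequence (list aligned with
    ``sequences``, or a dict keyed like a parallel accession list is not
    accepted here — pass values in sequence order). Sequences are ranked
    ascending by sum with average ranks on ties, so positive Z means
    association with high binding. Residues present in none or all sequences
    get no Z. With < 3 sequences or constant sums the matrix is degenerate.
    """
    length = _check_equal_length(sequences)
    values = np.asarray(
        list(sums.values()) if isinstance(sums, dict) else sums, dtype=float
    )
    if len(values) != len(sequences):
        raise ValueError("need exactly one sum per sequence")
    if len(sequences) < 3:
        raise ValueError("need at least 3 sequences")
    n = len(sequences)
    residues = sorted({ch for s in sequences for ch in s})
    z = pd.DataFrame(np.nan, index=np.arange(1, length + 1), columns=residues)
    counts = pd.DataFrame(0, index=z.index, columns=residues)
    degenerate = bool(np.all(values == values[0]))
    ranks = stats.rankdata(values, method="average")
    for pos in range(length):
        col = np.array([s[pos] for s in sequences])
        for res in np.unique(col):
            carrier = col == res
            n_r = int(carrier.sum())
            counts.loc[pos + 1, res] = n_r
            if n_r == 0 or n_r == n or degenerate:
                continue
            w = float(ranks[carrier].sum())
            mean = n_r * (n + 1) / 2.0
            sd = np.sqrt(n_r * (n - n_r) * (n + 1) / 12.0)
            z.loc[pos + 1, res] = (w - mean) / sd
    return ResidueAssociationMatrix(z=z, counts=counts, degenerate=degenerate)


def significance_mask(
    matrix: ResidueAssociationMatrix, alpha: float = 0.05
) -> pd.DataFrame:
    """BH-corrected two-sided significance mask over all defined Z-scores.

    Fills ``matrix.pvalues``, ``matrix.corrected`` and ``matrix.mask`` and
    returns the mask (True where corrected p <= alpha).
    """
    z = matrix.z
    zv = z.to_numpy()
    defined = ~np.isnan(zv)
    p_arr = np.full(zv.shape, np.nan)
    adj_arr = np.full(zv.shape, np.nan)
    mask_arr = np.zeros(zv.shape, dtype=bool)
    flat_p = 2.0 * stats.norm.sf(np.abs(zv[defined]))
    p_arr[defined] = flat_p
    if flat_p.size:
        reject, _ = bh_call(flat_p, alpha=alpha)
        m = flat_p.size
        order = np.argsort(flat_p, kind="stable")
        stepped = flat_p[order] * m / np.arange(1, m + 1)
        adj_sorted = np.minimum(np.minimum.accumulate(stepped[::-1])[::-1], 1.0)
        adj_full = np.empty(m)
        adj_full[order] = adj_sorted
        adj_arr[defined] = adj_full
        mask_arr[defined] = reject
    matrix.pvalues = pd.DataFrame(p_arr, index=z.index, columns=z.columns)
    matrix.corrected = pd.DataFrame(adj_arr, index=z.index, columns=z.columns)
    matrix.mask = pd.DataFrame(mask_arr, index=z.index, columns=z.columns)
    return matrix.mask
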