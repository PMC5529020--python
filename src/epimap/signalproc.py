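"""Replicate collapsing, re-incubation correction and running-median profiles.

The raw data are two per-field intensity recordings (naive-IgG background and
antivenom). Per peptide, the replicate fields are collapsed to a median in
each channel; the sticky corner-control fields are excluded and returned as
two empirical distributions. The ratio of corner channel medians estimates
the multiplicative re-incubation effect, which is removed as

    corrected = antivenom_median - factor * background_median

(negative values are kept: the downstream Z-test needs the full null
distribution). Per-toxin profiles index corrected scores by the 1-based
N-terminal position of each 15-mer and are smoothed with a 3-wide running
median (terminal positions use the mean of the two available values, which
preserves profile length).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .library import ArrayLayout, PeptideLibrary, ToxinRecord


@dataclass
class PeptideSignal:
    """Channel medians and corrected score of one unique peptide."""

    peptide: str
    background_median: float
    antivenom_median: float
    corrected: float


@dataclass
class SignalProfile:
    """Per-toxin score profile indexed by 15-mer N-terminal position (1-based).

    ``scores`` holds the running-median-smoothed corrected scores
    (length ``L - 14``); ``raw`` the unsmoothed corrected scores.
    """

    accession: str
    scores: np.ndarray
    raw: np.ndarray = field(default=None)  # type: ignore[assignment]
    window: int = 3

    def __len__(self) -> int:
        return len(self.scores)


def replicate_median(
    table: pd.DataFrame, layout: ArrayLayout
) -> tuple[pd.Series, np.ndarray]:
    """Collapse one channel's fields to per-peptide medians.

    Corner-control fields are excluded from peptide medians and returned
    separately as an empirical intensity distribution. Raises if a layout
    peptide has no field in the table.
    """
    lay = pd.DataFrame(
        layout.fields, columns=["field_id", "peptide", "is_corner"]
    )
    merged = lay.merge(table[["field_id", "intensity"]], on="field_id", how="left")
    merged = merged.dropna(subset=["intensity"])  # lost replicates tolerated
    corner_values = merged.loc[merged["is_corner"], "intensity"].to_numpy()
    medians = (
        merged.loc[~merged["is_corner"]]
        .groupby("peptide", sort=False)["intensity"]
        .median()
    )
    expected = {p for _, p, c in layout.fields if not c}
    absent = expected - set(medians.index)
    if absent:
        raise ValueError(f"peptide {sorted(absent)[0]!r} missing from the table")
    return medians, corner_values


def channel_medians(
    background: pd.DataFrame, antivenom: pd.DataFrame, layout: ArrayLayout
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Per-peptide medians for both recordings plus the corner distributions."""
    bg_med, corner_bg = replicate_median(background, layout)
    av_med, corner_av = replicate_median(antivenom, layout)
    table = pd.DataFrame(
        {"background_median": bg_med, "antivenom_median": av_med}
    )
    return table, corner_bg, corner_av


def estimate_reincubation(
    corner_background: np.ndarray, corner_antivenom: np.ndarray
) -> float:
    """Re-incubation factor: ratio of corner-peptide channel medians."""
    corner_background = np.asarray(corner_background, dtype=float)
    corner_antivenom = np.asarray(corner_antivenom, dtype=float)
    if corner_background.size == 0 or corner_antivenom.size == 0:
        raise ValueError("corner distributions must be non-empty")
    denom = float(np.median(corner_background))
    if denom <= 0:
        raise ValueError("corner background median must be > 0")
    return float(np.median(corner_antivenom)) / denom


def correct_signal(antivenom_median, background_median, factor: float):
    """Remove the re-incubation background: ``av - factor * bg`` (no clamp)."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    return np.asarray(antivenom_median, dtype=float) - factor * np.asarray(
        background_median, dtype=float
    )


def corrected_peptide_signals(
    medians: pd.DataFrame, factor: float
) -> pd.Series:
    """Corrected score per unique peptide (index: peptide string)."""
    return pd.Series(
        correct_signal(
            medians["antivenom_median"], medians["background_median"], factor
        ),
        index=medians.index,
        name="corrected",
    )


def running_median(scores: np.ndarray) -> np.ndarray:
    """3-wide running median; terminal positions use the 2-value median.

    Interior position i -> median(x[i-1], x[i], x[i+1]); the first and last
    positions take the median (= mean) of the two available values, keeping
    the output the same length as the input. Length-1 input is returned as is.
    """
    x = np.asarray(scores, dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("profile must have length >= 1")
    if n == 1:
        return x.copy()
    out = np.empty(n)
    out[0] = 0.5 * (x[0] + x[1])
    out[-1] = 0.5 * (x[-2] + x[-1])
    if n > 2:
        stacked = np.stack([x[:-2], x[1:-1], x[2:]])
        out[1:-1] = np.median(stacked, axis=0)
    return out


def map_to_toxins(
    peptide_scores: Mapping[str, float] | pd.Series,
    toxins: list[ToxinRecord],
    library: PeptideLibrary | None = None,
    k: int = 15,
) -> list[SignalProfile]:
    """Map corrected peptide scores onto each toxin and smooth.

    A peptide shared by several toxins contributes its single corrected score
    at every origin position. Toxins shorter than ``k`` yield no profile.
    """
    if library is not None:
        k = library.k
    profiles: list[SignalProfile] = []
    for toxin in toxins:
        n = len(toxin.sequence) - k + 1
        if n < 1:
            continue
        raw = np.array(
            [peptide_scores[toxin.sequence[i : i + k]] for i in range(n)],
            dtype=float,
        )
        profiles.append(
            SignalProfile(
                accession=toxin.accession, scores=running_median(raw), raw=raw
            )
        )
    return profiles
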