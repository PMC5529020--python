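"""Bootstrap-calibrated significance calling for running-median scores.

The null standard deviation is estimated conservatively from the corner
control peptides, whose unspecific binding is at least as noisy as that of
library peptides: each bootstrap repetition builds three neighbouring
pseudo-peptides (replicate draws from the two empirical corner
distributions, channel medians, re-incubation correction) and takes their
3-window running median, mirroring every transformation applied to real
scores. One-sided Z-test p-values (null mean 0) over the deduplicated
(peptide, running-median) pairs are then corrected with the
Benjamini-Hochberg step-up at the chosen FDR level; the smallest significant
score becomes the array-wide score threshold. A toxin is called recognized
when at least two successive 15-mers pass that threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .signalproc import SignalProfile


@dataclass
class SignificanceModel:
    """Fitted null model and the derived score threshold."""

    sigma: float
    n_boot: int = 50_000
    alpha: float = 0.05
    score_threshold: float = float("inf")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def bootstrap_sigma(
    corner_background: np.ndarray,
    corner_antivenom: np.ndarray,
    factor: float,
    n_boot: int = 50_000,
    replicates: int = 5,
    seed: int = 0,
    window: int = 3,
) -> float:
    """Bootstrap SD of the corrected running-median score under the null.

    Per repetition, ``window`` neighbouring pseudo-peptides are built by
    drawing ``replicates`` values with replacement from each corner channel
    distribution, taking channel medians, forming the corrected score, and
    taking the running median across the pseudo-peptides. Returns the
    standard deviation over ``n_boot`` repetitions.
    """
    bg = np.asarray(corner_background, dtype=float)
    av = np.asarray(corner_antivenom, dtype=float)
    if bg.size == 0 or av.size == 0:
        raise ValueError("corner distributions must be non-empty")
    rng = np.random.default_rng(seed)
    shape = (n_boot, window, replicates)
    bg_med = np.median(rng.choice(bg, size=shape), axis=2)
    av_med = np.median(rng.choice(av, size=shape), axis=2)
    corrected = av_med - factor * bg_med
    scores = np.median(corrected, axis=1)
    return float(np.std(scores))


def z_pvalues(scores: np.ndarray, sigma: float) -> np.ndarray:
    """One-sided (upper-tail) standard-normal p-values of scores / sigma."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return stats.norm.sf(np.asarray(scores, dtype=float) / sigma)


def bh_call(
    pvalues: np.ndarray, alpha: float = 0.05, scores: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up: reject the largest k with p_(k) <= k*a/m.

    Returns the rejection mask and, if ``scores`` is given, the smallest
    significant score (``+inf`` when nothing is rejected).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), float("inf")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= (np.arange(1, m + 1) * alpha / m)
    if not below.any():
        return np.zeros(m, dtype=bool), float("inf")
    k = int(np.max(np.nonzero(below)[0]))
    mask = p <= ranked[k]
    threshold = float("inf")
    if scores is not None:
        threshold = float(np.min(np.asarray(scores, dtype=float)[mask]))
    return mask, threshold


def fit_significance(
    profiles: list[SignalProfile],
    sigma: float,
    alpha: float = 0.05,
    n_boot: int = 50_000,
    seed: int = 0,
    toxin_sequences: dict[str, str] | None = None,
    k: int = 15,
) -> SignificanceModel:
    """Fit the score threshold by BH over unique (peptide, score) pairs.

    The BH family is the set of deduplicated peptide-running-median pairs
    across all profiles (the same peptide can carry different running
    medians in different sequence contexts). ``toxin_sequences`` maps
    accession -> sequence and is required to recover the peptide strings.
    """
    if toxin_sequences is None:
        raise ValueError("toxin_sequences mapping is required")
    pairs: set[tuple[str, float]] = set()
    for prof in profiles:
        seq = toxin_sequences[prof.accession]
        for i, s in enumerate(prof.scores):
            pairs.add((seq[i : i + k], float(s)))
    scores = np.array([s for _, s in pairs])
    pvals = z_pvalues(scores, sigma)
    _, threshold = bh_call(pvals, alpha=alpha, scores=scores)
    return SignificanceModel(
        sigma=sigma,
        n_boot=n_boot,
        alpha=alpha,
        score_threshold=threshold,
        seed=seed,
    )


def significant_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) 1-based inclusive positions."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(np.asarray(mask, dtype=bool)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start + 1, i))
            start = None
    if start is not None:
        runs.append((start + 1, len(mask)))
    return runs


def call_recognized(
    profiles: list[SignalProfile], model: SignificanceModel
) -> dict[str, dict]:
    """Call each toxin recognized iff >= 2 successive positions are significant.

    Returns, per accession: ``recognized`` (bool), ``mask`` (per-position
    significance) and ``runs`` (maximal significant runs, 1-based inclusive).
    """
    calls: dict[str, dict] = {}
    for prof in profiles:
        mask = prof.scores >= model.score_threshold
        runs = significant_runs(mask)
        calls[prof.accession] = {
            "recognized": any(b - a + 1 >= 2 for a, b in runs),
            "mask": mask,
            "runs": runs,
        }
    return calls
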