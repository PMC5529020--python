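"""Synthetic toxin sets and two-recording array intensities with ground truth.

The generator emulates the statistical structure the analysis assumes:

* toxin families built from a random ancestor plus per-site substitutions
  (equal lengths within a family, so the identity alignment is a valid
  gap-free MSA for that family);
* planted epitope motifs (4-12 residues, the typical span of a linear
  epitope element) written into a subset of carrier toxins at a shared
  position, which elevates the antivenom signal of every 15-mer containing
  the motif;
* log-normal per-field unspecific binding, heavier-tailed for the sticky
  corner-control peptide;
* a multiplicative re-incubation effect inflating the second (antivenom)
  recording relative to the first (naive-IgG background) recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import STANDARD_RESIDUES, ArrayLayout, ToxinRecord

#: Default protein-family mixture (fractions of the toxin set), mirroring the
#: dominance of metalloproteases, phospholipases and serine proteases in pit
#: viper venoms.
DEFAULT_FAMILY_MIX = {"SVMP": 0.4, "PLA2": 0.35, "SVSP": 0.25}


@dataclass
class PlantedEpitope:
    """Ground truth for one planted linear epitope element.

    ``positions`` maps each carrier accession to the 1-based start of the
    motif within that carrier's sequence.
    """

    motif: str
    carrier_accessions: frozenset[str]
    effect_size: float
    family: str = ""
    positions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 4 <= len(self.motif) <= 12:
            raise ValueError("motif length must be between 4 and 12 residues")


@dataclass
class NoiseModel:
    """Log-normal field-noise parameters and the re-incubation effect.

    Intensities are in arbitrary fluorescence units (AFU). Defaults put the
    background median at ~50 AFU, corner controls at ~150 AFU with a heavier
    right tail, and a 4.3-fold second-incubation inflation.
    """

    background_log_mean: float = math.log(50.0)
    background_log_sd: float = 0.5
    reincubation_factor: float = 4.3
    corner_log_mean: float = math.log(150.0)
    corner_log_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_log_sd < 0 or self.corner_log_sd < 0:
            raise ValueError("log-sd parameters must be >= 0")
        if self.reincubation_factor <= 0:
            raise ValueError("reincubation_factor must be > 0")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    letters = np.array(list(STANDARD_RESIDUES))
    return "".join(rng.choice(letters, size=length))


def _mutate(rng: np.random.Generator, ancestor: str, rate: float) -> str:
    """Substitute each site with probability ``rate`` (never to itself)."""
    seq = list(ancestor)
    letters = list(STANDARD_RESIDUES)
    for i in range(len(seq)):
        if rng.random() < rate:
            choices = [a for a in letters if a != seq[i]]
            seq[i] = choices[rng.integers(len(choices))]
    return "".join(seq)


def simulate_toxin_set(
    n_toxins: int = 100,
    family_mix: dict[str, float] | None = None,
    length_range: tuple[int, int] = (60, 160),
    n_epitopes: int = 0,
    effect_size: float = 0.0,
    seed: int = 0,
    motif_length_range: tuple[int, int] = (4, 12),
    carrier_fraction: float = 0.6,
    divergence: float = 0.3,
) -> tuple[list[ToxinRecord], list[PlantedEpitope]]:
    """Generate a toxin set with planted epitope motifs and its truth list.

    Each family shares an ancestor sequence of a single length drawn from
    ``length_range``; members diverge by independent substitutions at rate
    ``divergence``. Each planted epitope picks a family, a motif of random
    length in ``motif_length_range`` and a shared in-sequence position, and
    overwrites that window in a random ``carrier_fraction`` subset of the
    family (at least one carrier). Same seed, same output.

    Returns the toxin records and the ground-truth list of planted epitopes.
    Raises if a motif cannot fit the target family's sequence length.
    """
    if n_toxins < 1:
        raise ValueError("n_toxins must be >= 1")
    if length_range[0] < 15:
        raise ValueError("minimum toxin length is 15 (one peptide window)")
    family_mix = dict(family_mix or DEFAULT_FAMILY_MIX)
    rng = np.random.default_rng(seed)

    # integer family sizes summing to n_toxins, largest-remainder rounding
    names = list(family_mix)
    weights = np.array([family_mix[f] for f in names], dtype=float)
    weights /= weights.sum()
    sizes = np.floor(weights * n_toxins).astype(int)
    for i in np.argsort(-(weights * n_toxins - sizes)):
        if sizes.sum() == n_toxins:
            break
        sizes[i] += 1

    toxins: list[ToxinRecord] = []
    members: dict[str, list[int]] = {}
    lengths: dict[str, int] = {}
    idx = 0
    for fam, size in zip(names, sizes):
        if size == 0:
            continue
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        lengths[fam] = length
        ancestor = _random_sequence(rng, length)
        members[fam] = []
        for _ in range(size):
            acc = f"SYN{idx:04d}"
            toxins.append(
                ToxinRecord(
                    accession=acc,
                    species=f"Synthetivipera sp{idx % 7}",
                    family=fam,
                    is_partial=False,
                    sequence=_mutate(rng, ancestor, divergence),
                )
            )
            members[fam].append(idx)
            idx += 1

    epitopes: list[PlantedEpitope] = []
    occupied: dict[str, list[tuple[int, int]]] = {f: [] for f in members}
    for _ in range(n_epitopes):
        fam = names[int(rng.integers(len(names)))]
        while fam not in members:
            fam = names[int(rng.integers(len(names)))]
        mlen = int(rng.integers(motif_length_range[0], motif_length_range[1] + 1))
        if mlen > lengths[fam]:
            raise ValueError(
                f"motif length {mlen} exceeds family {fam} sequence length"
            )
        motif = _random_sequence(rng, mlen)
        # shared position, avoiding previously planted windows in the family
        start = None
        for _ in range(200):
            cand = int(rng.integers(1, lengths[fam] - mlen + 2))
            if all(
                cand + mlen - 1 < a or cand > b for a, b in occupied[fam]
            ):
                start = cand
                break
        if start is None:
            raise ValueError(f"no room left to plant a motif in family {fam}")
        occupied[fam].append((start, start + mlen - 1))
        n_carriers = max(1, int(round(carrier_fraction * len(members[fam]))))
        chosen = rng.choice(members[fam], size=n_carriers, replace=False)
        positions: dict[str, int] = {}
        for j in sorted(chosen):
            t = toxins[j]
            seq = t.sequence[: start - 1] + motif + t.sequence[start - 1 + mlen :]
            toxins[j] = ToxinRecord(
                accession=t.accession,
                species=t.species,
                family=t.family,
                subgroup=t.subgroup,
                is_partial=t.is_partial,
                sequence=seq,
            )
            positions[t.accession] = start
        epitopes.append(
            PlantedEpitope(
                motif=motif,
                carrier_accessions=frozenset(positions),
                effect_size=effect_size,
                family=fam,
                positions=positions,
            )
        )
    return toxins, epitopes


def simulate_intensities(
    layout: ArrayLayout,
    truth: list[PlantedEpitope],
    noise: NoiseModel,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the two array recordings for a layout.

    Returns ``(background, antivenom)`` tables with columns
    ``field_id, peptide, intensity``; every layout field appears exactly once
    in each table.

    Background recording: log-normal unspecific binding per field (corner
    fields use the heavier corner distribution). Antivenom recording: a fresh
    independent unspecific draw inflated by the re-incubation factor, plus the
    planted effect size for every non-corner field whose peptide contains a
    planted motif. Antivenom-channel unspecific binding is an independent
    draw rather than a copy of the background draw: the analysis corrects
    with channel medians, not per-field pairing, so independence is the
    conservative model.
    """
    rng = np.random.default_rng(noise.seed)
    fids = np.array([f[0] for f in layout.fields])
    peptides = np.array([f[1] for f in layout.fields])
    corner = np.array([f[2] for f in layout.fields], dtype=bool)
    n = len(fids)

    # per-unique-peptide planted elevation (sum over motifs contained)
    uniq = pd.unique(peptides[~corner])
    elevation = {p: 0.0 for p in uniq}
    for ep in truth:
        for p in uniq:
            if ep.motif in p:
                elevation[p] += ep.effect_size
    effect = np.where(
        corner, 0.0, np.array([elevation.get(p, 0.0) for p in peptides])
    )

    def draw(channel_rng: np.random.Generator) -> np.ndarray:
        base = channel_rng.lognormal(
            noise.background_log_mean, noise.background_log_sd, size=n
        )
        sticky = channel_rng.lognormal(
            noise.corner_log_mean, noise.corner_log_sd, size=n
        )
        return np.where(corner, sticky, base)

    background = draw(rng)
    antivenom = noise.reincubation_factor * draw(rng) + effect

    bg = pd.DataFrame(
        {"field_id": fids, "peptide": peptides, "intensity": background}
    )
    av = pd.DataFrame(
        {"field_id": fids, "peptide": peptides, "intensity": antivenom}
    )
    return bg, av
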