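"""Reusable calibration experiments over the synthetic generator.

These drive the full pipeline over many simulated arrays to measure its
operating characteristics: the false-discovery proportion on null arrays
(no planted epitopes, so every significant call is false) and the recovery
rate of planted epitope segments. Both are pure functions of their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epitopes import extract_core_motif, find_shared_segments, map_profiles_to_msa
from .library import assign_layout, build_library
from .pipeline import analyze_array
from .simulate import NoiseModel, simulate_intensities, simulate_toxin_set


def _array_seeds(base_seed: int, index: int, n: int = 4) -> list[int]:
    state = np.random.SeedSequence([base_seed, index]).generate_state(
        n, dtype=np.uint32
    )
    return [int(s & 0x7FFFFFFF) for s in state]


@dataclass
class NullFdrResult:
    mean_fdp: float  # mean false-discovery proportion over arrays
    mean_call_fraction: float  # mean fraction of pairs called significant
    n_arrays: int
    rejections: list[int]


def null_fdr_experiment(
    n_arrays: int = 200,
    n_toxins: int = 100,
    length_range: tuple[int, int] = (30, 38),
    replicates: int = 5,
    corner_field_count: int = 200,
    n_boot: int = 50_000,
    alpha: float = 0.05,
    seed: int = 1,
) -> NullFdrResult:
    """Empirical FDR of the full calling pipeline on null synthetic arrays.

    Each array is simulated with zero planted epitopes, pushed through
    replicate medians, re-incubation correction, running medians, the
    bootstrap-calibrated one-sided Z-test and BH at ``alpha``. All calls are
    false by construction, so the per-array false-discovery proportion is 1
    when anything is rejected (0 otherwise) and the mean over arrays
    estimates the pipeline's FDR.
    """
    fdps, fractions, rejections = [], [], []
    for i in range(n_arrays):
        seeds = _array_seeds(seed, i)
        toxins, _ = simulate_toxin_set(
            n_toxins=n_toxins,
            length_range=length_range,
            n_epitopes=0,
            seed=seeds[0],
        )
        library = build_library(toxins)
        layout = assign_layout(
            library,
            replicates=replicates,
            corner_field_count=corner_field_count,
            seed=seeds[1],
        )
        background, antivenom = simulate_intensities(
            layout, [], NoiseModel(seed=seeds[2])
        )
        result = analyze_array(
            background,
            antivenom,
            layout,
            toxins,
            alpha=alpha,
            n_boot=n_boot,
            replicates=replicates,
            seed=seeds[3],
        )
        threshold = result["model"].score_threshold
        pairs = {
            (seq[j : j + 15], float(s))
            for prof in result["profiles"]
            for seq in [result["sequences"][prof.accession]]
            for j, s in enumerate(prof.scores)
        }
        n_rejected = sum(1 for _, s in pairs if s >= threshold)
        rejections.append(n_rejected)
        fdps.append(1.0 if n_rejected else 0.0)  # all rejections are false
        fractions.append(n_rejected / len(pairs))
    return NullFdrResult(
        mean_fdp=float(np.mean(fdps)),
        mean_call_fraction=float(np.mean(fractions)),
        n_arrays=n_arrays,
        rejections=rejections,
    )


@dataclass
class RecoveryResult:
    recovery_rate: float  # fraction of simulations with an overlapping segment
    core_law_violations: int  # cases where |core| != 15 - run + 1
    n_simulations: int
    n_segments_total: int


def planted_recovery_experiment(
    n_simulations: int = 100,
    n_toxins: int = 40,
    length_range: tuple[int, int] = (60, 90),
    effect_sigma_multiple: float = 5.0,
    min_share: int = 10,
    replicates: int = 5,
    corner_field_count: int = 200,
    n_boot: int = 20_000,
    alpha: float = 0.05,
    seed: int = 1,
    carrier_fraction: float = 0.5,
) -> RecoveryResult:
    """Recovery rate of planted epitope segments at a given effect strength.

    The planted effect size is ``effect_sigma_multiple`` times a reference
    null SD obtained by bootstrapping the default corner noise model once.
    Per simulation, one motif is planted in ``carrier_fraction`` of a family
    (>= ``min_share`` carriers enforced by construction) and recovery means
    a reported shared segment overlapping the planted columns. Every
    extracted core is checked against the intersection-length law
    ``|core| = 15 - run + 1``.
    """
    from .significance import bootstrap_sigma

    # reference sigma for the default corner noise model
    ref_rng = np.random.default_rng(np.random.SeedSequence([seed, 999_983]))
    noise0 = NoiseModel()
    corner_bg = ref_rng.lognormal(
        noise0.corner_log_mean, noise0.corner_log_sd, size=852
    )
    corner_av = noise0.reincubation_factor * ref_rng.lognormal(
        noise0.corner_log_mean, noise0.corner_log_sd, size=852
    )
    sigma_ref = bootstrap_sigma(
        corner_bg, corner_av, noise0.reincubation_factor, n_boot=50_000,
        seed=int(ref_rng.integers(2**31)),
    )
    effect = effect_sigma_multiple * sigma_ref

    recovered = 0
    violations = 0
    n_segments = 0
    for i in range(n_simulations):
        seeds = _array_seeds(seed, i)
        toxins, truth = simulate_toxin_set(
            n_toxins=n_toxins,
            family_mix={"FAM": 1.0},
            length_range=length_range,
            n_epitopes=1,
            effect_size=effect,
            seed=seeds[0],
            carrier_fraction=carrier_fraction,
        )
        assert len(truth[0].carrier_accessions) >= min_share
        library = build_library(toxins)
        layout = assign_layout(
            library,
            replicates=replicates,
            corner_field_count=corner_field_count,
            seed=seeds[1],
        )
        background, antivenom = simulate_intensities(
            layout, truth, NoiseModel(seed=seeds[2])
        )
        result = analyze_array(
            background,
            antivenom,
            layout,
            toxins,
            alpha=alpha,
            n_boot=n_boot,
            replicates=replicates,
            seed=seeds[3],
        )
        threshold = result["model"].score_threshold
        if not np.isfinite(threshold):
            continue
        msa = {t.accession: t.sequence for t in toxins}  # equal-length family
        aligned = map_profiles_to_msa(result["profiles"], msa)
        segments = find_shared_segments(aligned, threshold, min_share=min_share)
        n_segments += len(segments)
        # planted columns = start positions of 15-mers containing the motif
        # (where the elevated signal is anchored), by substring scan
        ep = truth[0]
        carrier = next(iter(ep.carrier_accessions))
        seq = msa[carrier]
        planted_cols = {
            t
            for t in range(1, len(seq) - 14 + 1)
            if ep.motif in seq[t - 1 : t + 14]
        }
        hit = False
        for segment in segments:
            cols = set(range(segment.start_col, segment.end_col + 1))
            if cols & planted_cols:
                hit = True
            core = extract_core_motif(
                segment, aligned, result["profiles"], threshold,
                result["sequences"],
            )
            if len(core.core) != 15 - core.run_length + 1:
                violations += 1
        if hit:
            recovered += 1
    return RecoveryResult(
        recovery_rate=recovered / n_simulations,
        core_law_violations=violations,
        n_simulations=n_simulations,
        n_segments_total=n_segments,
    )
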