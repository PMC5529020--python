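"""End-to-end orchestration: simulate/load -> design -> process -> call ->
epitopes -> logos (-> paint), with a serialized manifest per run.

``analyze_array`` is the in-memory workhorse (two intensity tables in,
profiles + significance model + per-toxin calls out); ``run_pipeline``
drives a full run from a :class:`RunConfig` and writes every intermediate
as a TSV under the run directory. All randomness derives from one global
seed fanned out to stage-specific child seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .association import logo_matrix, residue_zscores, significance_mask
from .epitopes import (
    CoreMotif,
    collect_similar,
    extract_core_motif,
    find_shared_segments,
    map_profiles_to_msa,
)
from .library import ArrayLayout, ToxinRecord, assign_layout, build_library
from .signalproc import (
    channel_medians,
    corrected_peptide_signals,
    estimate_reincubation,
    map_to_toxins,
)
from .significance import bootstrap_sigma, call_recognized, fit_significance
from .simulate import NoiseModel, simulate_intensities, simulate_toxin_set

logger = logging.getLogger("epimap")


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run.

    Defaults match the array design and calling constants used throughout:
    15-mer windows, 5 replicates, 852 corner fields, 50,000 bootstrap
    repetitions, FDR level 0.05, sharing threshold 10 toxins, 3 tolerated
    mismatches, 3-wide running median. When ``fasta`` is None the synthetic
    generator provides the inputs.
    """

    out_dir: str = "results/run"
    # file-driven inputs (all-or-nothing); when fasta is None, simulate
    fasta: str | None = None
    metadata: str | None = None
    background: str | None = None
    antivenom: str | None = None
    layout_path: str | None = None
    msa_dir: str | None = None
    structures: dict[str, dict] = field(default_factory=dict)
    # synthetic-generation parameters
    n_toxins: int = 100
    family_mix: dict[str, float] | None = None
    length_range: tuple[int, int] = (60, 160)
    n_epitopes: int = 3
    effect_size: float = 1500.0
    carrier_fraction: float = 0.6
    # analysis parameters
    k: int = 15
    replicates: int = 5
    corner_field_count: int = 852
    n_boot: int = 50_000
    alpha: float = 0.05
    min_share: int = 10
    max_mismatch: int = 3
    window: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if isinstance(cfg.length_range, list):
            cfg.length_range = tuple(cfg.length_range)
        return cfg


def child_seeds(seed: int, n: int) -> list[int]:
    """Fan one global seed out into n reproducible child seeds (< 2^31)."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def analyze_array(
    background: pd.DataFrame,
    antivenom: pd.DataFrame,
    layout: ArrayLayout,
    toxins: list[ToxinRecord],
    alpha: float = 0.05,
    n_boot: int = 50_000,
    replicates: int = 5,
    seed: int = 0,
    k: int = 15,
) -> dict:
    """Run replicate medians -> correction -> profiles -> calling in memory.

    Returns a dict with the per-peptide medians, corner distributions,
    re-incubation factor, corrected scores, smoothed profiles, fitted
    :class:`~epimap.significance.SignificanceModel` and per-toxin calls.
    """
    medians, corner_bg, corner_av = channel_medians(background, antivenom, layout)
    factor = estimate_reincubation(corner_bg, corner_av)
    corrected = corrected_peptide_signals(medians, factor)
    profiles = map_to_toxins(corrected, toxins, k=k)
    sigma = bootstrap_sigma(
        corner_bg,
        corner_av,
        factor,
        n_boot=n_boot,
        replicates=replicates,
        seed=seed,
    )
    sequences = {t.accession: t.sequence for t in toxins}
    model = fit_significance(
        profiles,
        sigma,
        alpha=alpha,
        n_boot=n_boot,
        seed=seed,
        toxin_sequences=sequences,
        k=k,
    )
    calls = call_recognized(profiles, model)
    return {
        "medians": medians,
        "corner_background": corner_bg,
        "corner_antivenom": corner_av,
        "factor": factor,
        "corrected": corrected,
        "profiles": profiles,
        "sigma": sigma,
        "model": model,
        "calls": calls,
        "sequences": sequences,
    }


def summarize_recognition(
    calls: dict[str, dict], toxins: list[ToxinRecord]
) -> pd.DataFrame:
    """Species x family table of toxin counts and recognized fractions.

    Cells with no toxins are simply absent (groupby semantics), not zero.
    """
    rows = [
        {
            "species": t.species,
            "family": t.family,
            "recognized": bool(calls[t.accession]["recognized"])
            if t.accession in calls
            else False,
        }
        for t in toxins
    ]
    frame = pd.DataFrame(rows)
    grouped = (
        frame.groupby(["species", "family"])["recognized"]
        .agg(n_toxins="size", n_recognized="sum")
        .reset_index()
    )
    grouped["ratio"] = grouped["n_recognized"] / grouped["n_toxins"]
    return grouped


def _family_msas(
    toxins: list[ToxinRecord], msa_dir: str | None
) -> dict[str, dict[str, str]]:
    """Per-family MSA: from disk when provided, else the identity alignment.

    Synthetic families have equal-length members, so the identity alignment
    (rows = sequences, no gaps) is valid; unequal-length families without an
    MSA file are skipped with a warning.
    """
    out: dict[str, dict[str, str]] = {}
    families = sorted({t.family for t in toxins if t.family})
    for fam in families:
        members = [t for t in toxins if t.family == fam]
        path = None
        if msa_dir is not None:
            for ext in (".fasta", ".fa", ".aln", ".clustal"):
                cand = Path(msa_dir) / f"{fam}{ext}"
                if cand.exists():
                    path = cand
                    break
        if path is not None:
            out[fam] = eio.read_msa(path)
        elif len({len(t.sequence) for t in members}) == 1:
            out[fam] = {t.accession: t.sequence for t in members}
        else:
            logger.warning(
                "family %s: no MSA file and unequal lengths; epitope stage skipped",
                fam,
            )
    return out


def _write_profiles(profiles, sequences, k, path) -> int:
    rows = []
    for prof in profiles:
        seq = sequences[prof.accession]
        for i, s in enumerate(prof.scores):
            rows.append(
                {
                    "accession": prof.accession,
                    "position": i + 1,
                    "peptide": seq[i : i + k],
                    "corrected": prof.raw[i],
                    "running_median": s,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.4f")
    return len(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write tables plus a manifest; returns run dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = child_seeds(config.seed, 4)
    counts: dict[str, int] = {}

    # ---- inputs -----------------------------------------------------------
    if config.fasta is not None:
        toxins = eio.read_toxins(config.fasta, config.metadata)
        truth = []
        background = eio.read_intensities(config.background)
        antivenom = eio.read_intensities(config.antivenom)
        layout = eio.read_layout(config.layout_path)
        library = build_library(toxins, k=config.k)
    else:
        toxins, truth = simulate_toxin_set(
            n_toxins=config.n_toxins,
            family_mix=config.family_mix,
            length_range=config.length_range,
            n_epitopes=config.n_epitopes,
            effect_size=config.effect_size,
            seed=seeds[0],
            carrier_fraction=config.carrier_fraction,
        )
        library = build_library(toxins, k=config.k)
        layout = assign_layout(
            library,
            replicates=config.replicates,
            corner_field_count=config.corner_field_count,
            seed=seeds[1],
        )
        noise = NoiseModel(seed=seeds[2])
        background, antivenom = simulate_intensities(layout, truth, noise)
        eio.write_toxins(toxins, out / "toxins.fasta", out / "metadata.tsv")
        eio.write_intensities(background, out / "background.tsv")
        eio.write_intensities(antivenom, out / "antivenom.tsv")
        if truth:
            pd.DataFrame(
                [
                    {
                        "motif": ep.motif,
                        "carrier": acc,
                        "position": pos,
                        "effect_size": ep.effect_size,
                        "family": ep.family,
                    }
                    for ep in truth
                    for acc, pos in sorted(ep.positions.items())
                ]
            ).to_csv(out / "truth.tsv", sep="\t", index=False)

    eio.write_library(library, out / "library.tsv")
    eio.write_layout(layout, out / "layout.tsv")
    counts["toxins"] = len(toxins)
    counts["unique_peptides"] = len(library)
    counts["fields"] = len(layout)

    # ---- process + call ---------------------------------------------------
    result = analyze_array(
        background,
        antivenom,
        layout,
        toxins,
        alpha=config.alpha,
        n_boot=config.n_boot,
        replicates=config.replicates,
        seed=seeds[3],
        k=config.k,
    )
    sequences = result["sequences"]
    result["medians"].assign(corrected=result["corrected"]).to_csv(
        out / "peptide_signals.tsv", sep="\t", float_format="%.4f"
    )
    counts["profile_rows"] = _write_profiles(
        result["profiles"], sequences, config.k, out / "profiles.tsv"
    )
    model = result["model"]
    (out / "model.json").write_text(
        json.dumps(
            {
                "sigma": model.sigma,
                "n_boot": model.n_boot,
                "alpha": model.alpha,
                "score_threshold": (
                    model.score_threshold
                    if np.isfinite(model.score_threshold)
                    else None
                ),
                "reincubation_factor": result["factor"],
                "seed": model.seed,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    calls = result["calls"]
    pd.DataFrame(
        [
            {
                "accession": acc,
                "recognized": info["recognized"],
                "runs": ";".join(f"{a}-{b}" for a, b in info["runs"]),
            }
            for acc, info in calls.items()
        ]
    ).to_csv(out / "calls.tsv", sep="\t", index=False)
    summarize_recognition(calls, toxins).to_csv(
        out / "recognition_summary.tsv", sep="\t", index=False, float_format="%.4f"
    )
    counts["recognized_toxins"] = sum(
        1 for info in calls.values() if info["recognized"]
    )

    # ---- epitopes + logos -------------------------------------------------
    msas = _family_msas(toxins, config.msa_dir)
    seg_rows, core_rows, sum_rows = [], [], []
    all_cores: list[CoreMotif] = []
    prof_by_acc = {p.accession: p for p in result["profiles"]}
    for fam, msa in sorted(msas.items()):
        fam_profiles = [prof_by_acc[a] for a in msa if a in prof_by_acc]
        if not fam_profiles:
            continue
        aligned = map_profiles_to_msa(fam_profiles, msa)
        long = (
            aligned.column_scores.rename_axis("accession")
            .reset_index()
            .melt(id_vars="accession", var_name="column", value_name="score")
            .dropna()
        )
        long.insert(0, "family", fam)
        long.to_csv(
            out / f"aligned_profile_{fam}.tsv",
            sep="\t",
            index=False,
            float_format="%.4f",
        )
        if not np.isfinite(model.score_threshold):
            continue
        segments = find_shared_segments(
            aligned, model.score_threshold, min_share=config.min_share
        )
        for si, seg in enumerate(segments, start=1):
            seg_rows.append(
                {
                    "family": fam,
                    "segment": si,
                    "start_col": seg.start_col,
                    "end_col": seg.end_col,
                    "n_members": len(seg.member_toxins),
                    "members": ";".join(seg.member_toxins),
                }
            )
            core = extract_core_motif(
                seg, aligned, fam_profiles, model.score_threshold, sequences,
                k=config.k,
            )
            collect_similar(
                core, aligned, fam_profiles, sequences,
                max_mismatch=config.max_mismatch, k=config.k,
            )
            all_cores.append(core)
            core_rows.append(
                {
                    "family": fam,
                    "segment": si,
                    "core": core.core,
                    "top_accession": core.top_accession,
                    "run_start": core.run_start,
                    "run_length": core.run_length,
                    "n_similar": len(core.per_toxin_sum),
                }
            )
            for acc, total in sorted(core.per_toxin_sum.items()):
                sum_rows.append(
                    {
                        "family": fam,
                        "segment": si,
                        "accession": acc,
                        "sum_of_scores": total,
                    }
                )
            # logo + association over the matched core sequences
            pairs = []
            for acc in sorted(core.per_toxin_sum):
                a, b = core.per_toxin_span[acc]
                seq = sequences[acc][a - 1 : b]
                if len(seq) == len(core.core):
                    pairs.append((seq, core.per_toxin_sum[acc]))
            core_seqs = [s for s, _ in pairs]
            if len(core_seqs) >= 3:
                logo = logo_matrix(core_seqs)
                logo_long = (
                    logo.heights.rename_axis("position")
                    .reset_index()
                    .melt(id_vars="position", var_name="residue", value_name="height")
                )
                logo_long["information"] = logo_long["position"].map(
                    logo.information
                )
                logo_long.to_csv(
                    out / f"logo_{fam}_segment{si}.tsv",
                    sep="\t",
                    index=False,
                    float_format="%.4f",
                )
                assoc = residue_zscores(core_seqs, [v for _, v in pairs])
                if not assoc.degenerate:
                    significance_mask(assoc, alpha=config.alpha)
                    assoc_long = (
                        assoc.z.rename_axis("position")
                        .reset_index()
                        .melt(id_vars="position", var_name="residue", value_name="z")
                        .dropna()
                    )
                    mask_long = assoc.mask.rename_axis("position").reset_index().melt(
                        id_vars="position", var_name="residue", value_name="significant"
                    )
                    assoc_long = assoc_long.merge(
                        mask_long, on=["position", "residue"]
                    )
                    assoc_long.to_csv(
                        out / f"association_{fam}_segment{si}.tsv",
                        sep="\t",
                        index=False,
                        float_format="%.4f",
                    )
    pd.DataFrame(
        seg_rows,
        columns=["family", "segment", "start_col", "end_col", "n_members", "members"],
    ).to_csv(out / "segments.tsv", sep="\t", index=False)
    pd.DataFrame(
        core_rows,
        columns=[
            "family", "segment", "core", "top_accession", "run_start",
            "run_length", "n_similar",
        ],
    ).to_csv(out / "cores.tsv", sep="\t", index=False)
    pd.DataFrame(
        sum_rows, columns=["family", "segment", "accession", "sum_of_scores"]
    ).to_csv(out / "sums.tsv", sep="\t", index=False, float_format="%.4f")
    counts["segments"] = len(seg_rows)

    # ---- structures -------------------------------------------------------
    if config.structures:
        from .structure import residue_scores, write_scored_structure

        for acc, spec_ in config.structures.items():
            smap = residue_scores(all_cores, acc, chain=spec_.get("chain"))
            write_scored_structure(
                spec_["pdb"],
                smap,
                out / f"scored_{acc}.pdb",
                offset=int(spec_.get("offset", 0)),
                chain=spec_.get("chain"),
            )

    # ---- manifest ---------------------------------------------------------
    manifest = {
        "config": {
            key: (list(value) if isinstance(value, tuple) else value)
            for key, value in dataclasses.asdict(config).items()
        },
        "child_seeds": seeds,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "counts": counts,
        "reincubation_factor": result["factor"],
        "sigma": result["sigma"],
        "score_threshold": (
            model.score_threshold if np.isfinite(model.score_threshold) else None
        ),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    return out
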