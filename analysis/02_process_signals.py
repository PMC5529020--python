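#!/usr/bin/env python
"""Collapse replicates, estimate the re-incubation effect, build profiles.

Reads the simulated recordings, takes per-peptide medians over the five
replicate fields in each channel, estimates the re-incubation factor from
the corner-control fields (ratio of channel medians), corrects the
antivenom signal, and writes per-toxin running-median score profiles.
"""

from pathlib import Path

from epimap import io as eio
from epimap.signalproc import (
    channel_medians,
    corrected_peptide_signals,
    estimate_reincubation,
    map_to_toxins,
)

IN = Path("results/analysis/input")
OUT = Path("results/analysis")


def main() -> None:
    toxins = eio.read_toxins(IN / "toxins.fasta", IN / "metadata.tsv")
    layout = eio.read_layout(IN / "layout.tsv")
    background = eio.read_intensities(IN / "background.tsv")
    antivenom = eio.read_intensities(IN / "antivenom.tsv")

    medians, corner_bg, corner_av = channel_medians(background, antivenom, layout)
    factor = estimate_reincubation(corner_bg, corner_av)
    corrected = corrected_peptide_signals(medians, factor)
    profiles = map_to_toxins(corrected, toxins)

    medians.assign(corrected=corrected).to_csv(
        OUT / "peptide_signals.tsv", sep="\t", float_format="%.4f"
    )
    sequences = {t.accession: t.sequence for t in toxins}
    rows = []
    for prof in profiles:
        seq = sequences[prof.accession]
        for i, score in enumerate(prof.scores):
            rows.append(
                (prof.accession, i + 1, seq[i : i + 15], prof.raw[i], score)
            )
    import pandas as pd

    pd.DataFrame(
        rows,
        columns=["accession", "position", "peptide", "corrected", "running_median"],
    ).to_csv(OUT / "profiles.tsv", sep="\t", index=False, float_format="%.4f")

    print(f"corner fields per channel: {corner_bg.size}")
    print(f"estimated re-incubation factor: {factor:.3f} "
          "(generator truth: 4.3)")
    print(f"corrected scores: mean {corrected.mean():.2f}, "
          f"sd {corrected.std():.2f} AFU over {len(corrected)} peptides")
    print(f"profiles written for {len(profiles)} toxins -> {OUT}/profiles.tsv")


if __name__ == "__main__":
    main()
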