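#!/usr/bin/env python
"""Simulate a full-scale synthetic antivenom array experiment.

Generates ~100 toxins across the three dominant pit-viper toxin families
(SVMP, PLA2, SVSP) with three planted linear epitope motifs, designs the
15-mer tiling library with 5 randomized replicate fields per peptide plus
852 corner-control fields, and simulates the two recordings (naive-IgG
background and antivenom) with log-normal field noise and a 4.3-fold
re-incubation effect. Writes every input table under results/analysis/input.
"""

from pathlib import Path

import pandas as pd

from epimap import assign_layout, build_library
from epimap import io as eio
from epimap.simulate import NoiseModel, simulate_intensities, simulate_toxin_set

OUT = Path("results/analysis/input")
SEED = 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    toxins, truth = simulate_toxin_set(
        n_toxins=100,
        length_range=(60, 160),
        n_epitopes=3,
        effect_size=1500.0,
        seed=SEED,
    )
    library = build_library(toxins)
    layout = assign_layout(
        library, replicates=5, corner_field_count=852, seed=SEED + 1
    )
    background, antivenom = simulate_intensities(
        layout, truth, NoiseModel(seed=SEED + 2)
    )

    eio.write_toxins(toxins, OUT / "toxins.fasta", OUT / "metadata.tsv")
    eio.write_library(library, OUT / "library.tsv")
    eio.write_layout(layout, OUT / "layout.tsv")
    eio.write_intensities(background, OUT / "background.tsv")
    eio.write_intensities(antivenom, OUT / "antivenom.tsv")
    pd.DataFrame(
        [
            {
                "motif": ep.motif,
                "family": ep.family,
                "carrier": acc,
                "position": pos,
                "effect_size": ep.effect_size,
            }
            for ep in truth
            for acc, pos in sorted(ep.positions.items())
        ]
    ).to_csv(OUT / "truth.tsv", sep="\t", index=False)

    print(f"toxins:            {len(toxins)}")
    print(f"tiling windows:    {library.total_origins}")
    print(f"unique peptides:   {len(library)}")
    print(f"array fields:      {len(layout)} "
          f"({len(library)} x 5 replicates + 852 corner controls)")
    for ep in truth:
        print(
            f"planted motif {ep.motif} ({ep.family}): "
            f"{len(ep.carrier_accessions)} carriers, effect {ep.effect_size:.0f} AFU"
        )
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
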