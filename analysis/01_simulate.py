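#!/usr/bin/env python
"""Generate the synthetic study data set.

A 1000-gene genome organized in operons (1-5 genes, 200-6000 nt), true
elongation speeds log-uniform over 1-90 nt/s, half-lives of 1.5-20 min,
and steady-state observables (mRNA level, RNAP density) carrying 20%
multiplicative log-normal measurement noise, plus probe-level tracks at
25-nt spacing with smooth background drift. Per-gene tables go to
results/synthetic/; the bulky probe tracks go to scratch/tracks/.
"""

from pathlib import Path

import pandas as pd

import elongrate as eg
from elongrate import io

SEED = 20260922
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
TRACKS = Path(__file__).resolve().parents[1] / "scratch" / "tracks"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = eg.generate_genome(
        1000, operon_size_dist=(1, 5), length_dist=(200, 6000), seed=SEED
    )
    truth = eg.generate_truth(genome, noise_cv=0.2, seed=SEED + 1)
    meas, tracks = eg.generate_observables(
        genome, truth, seed=SEED + 2, probe_spacing=25, drift_amplitude=0.05,
        n_replicates=2,
    )
    io.write_genome_gff3(genome, OUT / "genome.gff3")
    io.write_tsv(meas, OUT / "measurements.tsv")
    io.write_tsv(
        pd.DataFrame(
            {
                "gene": truth.true_speed.index,
                "true_speed": truth.true_speed.to_numpy(),
                "true_activity": truth.true_activity.to_numpy(),
                "true_half_life_s": truth.true_half_life.to_numpy(),
            }
        ),
        OUT / "truth.tsv",
    )
    io.write_tsv(
        pd.DataFrame(
            {
                "gene": truth.true_half_life.index,
                "half_life": truth.true_half_life.to_numpy(),
                "unit": "s",
            }
        ),
        OUT / "half_lives.tsv",
    )
    TRACKS.mkdir(parents=True, exist_ok=True)
    for name, reps in tracks.items():
        io.write_tsv(pd.concat(reps, ignore_index=True), TRACKS / f"track_{name}.tsv")
    print(
        f"wrote {len(genome.genes)} genes in {len(genome.operons)} operons "
        f"({genome.genome_length/1e6:.2f} Mb) to {OUT}"
    )
    print(
        f"true speeds: median {truth.true_speed.median():.1f} nt/s, "
        f"range {truth.true_speed.min():.1f}-{truth.true_speed.max():.1f}"
    )


if __name__ == "__main__":
    main()
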