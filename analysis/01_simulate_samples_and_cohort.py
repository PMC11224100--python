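#!/usr/bin/env python
"""Simulate the study inputs: a batch of low-pass WGS bin-count samples
at known tumor fractions, and a 130-patient clinical cohort.

Writes per-sample bin tables (TSV), truth segments (BED + JSON sidecar)
and the cohort CSV under results/simulated/. Subsequent scripts consume
these files, so the whole analysis is reproducible from this seed.
"""

from pathlib import Path

from liquidfrac.genome_bins import GRCH38_AUTOSOMES, write_bin_table
from liquidfrac.pipeline import sample_seed
from liquidfrac.synthetic_data import (
    DEFAULT_GC_BIAS, simulate_cfdna_counts, simulate_cnv_profile,
    simulate_cohort, synthetic_grid, write_truth_sidecar,
)

SEED = 20260924
OUT = Path("results/simulated")
TUMOR_FRACTIONS = [0.0, 0.1, 0.2, 0.4]
SAMPLES_PER_TF = 2
CHROMS = [f"chr{i}" for i in range(1, 9)]  # ~3,100 bins at 500 kb


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sizes = {c: GRCH38_AUTOSOMES[c] for c in CHROMS}
    grid = synthetic_grid(sizes, seed=sample_seed(SEED, 10_000))
    i = 0
    for tf in TUMOR_FRACTIONS:
        for _ in range(SAMPLES_PER_TF):
            sid = f"S{i:03d}_tf{tf:g}"
            s = sample_seed(SEED, i)
            truth = simulate_cnv_profile(grid, tumor_fraction=tf,
                                         altered_genome_fraction=0.2, seed=s)
            counts = simulate_cfdna_counts(grid, truth, 500, DEFAULT_GC_BIAS,
                                           1000, seed=s + 1, sample_id=sid)
            write_bin_table(OUT / f"{sid}.tsv", grid, counts)
            truth.write_bed(OUT / f"{sid}.truth.bed")
            write_truth_sidecar(OUT / f"{sid}.truth.json", truth, s,
                                {"tumor_fraction": tf,
                                 "altered_genome_fraction": 0.2})
            i += 1
    cohort = simulate_cohort(130, seed=sample_seed(SEED, 20_000))
    cohort.to_csv(OUT / "cohort.csv", index=False)
    print(f"wrote {i} bin-count samples ({grid.n_bins} bins each) and a "
          f"{len(cohort)}-patient cohort to {OUT}/")


if __name__ == "__main__":
    main()
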