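import numpy as np
import pytest

from liquidfrac.ctdna_fraction import NormalizedProfile
from liquidfrac.synthetic_data import synthetic_grid


@pytest.fixture(scope="session")
def medium_grid():
    """~1,100-bin lattice over four synthetic chromosomes with GC and
    centromere annotation; big enough for the LOESS normalization path."""
    sizes = {f"chr{i}": 140_000_000 for i in range(1, 5)}
    return synthetic_grid(sizes, bin_size=500_000, seed=42)


@pytest.fixture(scope="session")
def small_grid():
    """~300-bin lattice (decile-median normalization path)."""
    sizes = {"chr1": 80_000_000, "chr2": 70_000_000}
    return synthetic_grid(sizes, bin_size=500_000, seed=7)


def make_profile(ratio, weight=300.0, chrom=None, centromere=None,
                 excluded=None, bin_size=500_000):
    """Hand-built NormalizedProfile for decoder/fit tests."""
    ratio = np.asarray(ratio, dtype=float)
    n = len(ratio)
    weight = np.full(n, float(weight)) if np.isscalar(weight) else np.asarray(weight)
    chrom = (np.array(["chr1"] * n, dtype=object) if chrom is None
             else np.asarray(chrom, dtype=object))
    centromere = (np.zeros(n, bool) if centromere is None
                  else np.asarray(centromere, bool))
    excluded = (np.zeros(n, bool) if excluded is None
                else np.asarray(excluded, bool))
    return NormalizedProfile(ratio=ratio, weight=weight, excluded=excluded,
                             chromosome=chrom, centromere_flag=centromere,
                             bin_size=bin_size)
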