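import numpy as np
import pandas as pd
import pytest

from cnvpop.genotypes import GenotypeMatrix
from cnvpop.intervals import GenomicInterval


def random_intervals(rng, n, n_chroms=2, span=10_000, max_len=500):
    """Random small intervals for oracle comparisons."""
    out = []
    for _ in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def make_matrix(dosage, populations=None, svtypes=None, spacing=1000):
    """GenotypeMatrix from a dense loci x samples array (NaN = missing)."""
    dosage = np.asarray(dosage, dtype=float)
    n_loci, n_samples = dosage.shape
    loci = pd.DataFrame(
        {
            "locus_id": [f"L{i}" for i in range(n_loci)],
            "chrom": ["chr1"] * n_loci,
            "start0": [i * spacing for i in range(n_loci)],
            "end0": [i * spacing + 100 for i in range(n_loci)],
            "svtype": svtypes or ["DEL"] * n_loci,
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{j}" for j in range(n_samples)],
            "population": populations or ["P1"] * n_samples,
        }
    )
    return GenotypeMatrix(loci, samples, dosage)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
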