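import numpy as np
import pytest

from fstscan.genotype_io import MISSING, GenotypeMatrix, LocusRecord, SampleRecord


def make_matrix(calls, cohorts=None, chrom=None, bp=None):
    """Small GenotypeMatrix from a call array (rows = samples)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_s, n_l = calls.shape
    cohorts = cohorts or ["c1"] * n_s
    samples = [SampleRecord(f"s{i}", cohorts[i]) for i in range(n_s)]
    loci = [
        LocusRecord(
            f"l{j}",
            chrom[j] if chrom else "1",
            bp[j] if bp else (j + 1) * 1000,
            "A",
            "B",
        )
        for j in range(n_l)
    ]
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls)


def both_alleles_observed(gm):
    """Mask of loci where both alleles appear among non-missing calls."""
    miss = gm.calls == MISSING
    has_b = (np.where(miss, 0, gm.calls) > 0).any(axis=0)
    has_a = (np.where(miss, 2, gm.calls) < 2).any(axis=0)
    return has_a & has_b


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
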