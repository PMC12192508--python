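import numpy as np
import pytest

from mndkit import (
    AncestryPanel,
    LocalAncestryMatrix,
    SimConfig,
    simulate_cohort,
    write_cohort,
)

PANEL = AncestryPanel()  # NAT/EUR/AFR


def make_matrix(calls, samples=None, chrom="chr1", panel=PANEL, pos=None):
    """Build a LocalAncestryMatrix from a (samples, sites, 2) call array."""
    calls = np.asarray(calls, dtype=np.int16)
    n_samples, n_sites, _ = calls.shape
    if samples is None:
        samples = [f"S{i + 1}" for i in range(n_samples)]
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    pos = np.asarray(pos)
    return LocalAncestryMatrix(
        samples=samples,
        chrom=np.array([chrom] * n_sites, dtype=object),
        pos=pos,
        ids=[f"{chrom}_{p}" for p in pos],
        calls=calls,
        panel=panel,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """20 founders + 5 pairs, desk scale, deterministic."""
    config = SimConfig(n_individuals=20, n_pairs=5, seed=7)
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("cohort")
    write_cohort(small_cohort, outdir)
    return outdir
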