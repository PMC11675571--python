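import numpy as np
import pytest

from haplodiv.core import HaplotypeMatrix
from haplodiv.simulate import SimulationConfig, simulate_locus

MODERN_GROUPS = ["AFR", "EUR", "ASN", "AMR"]


def small_matrix(alleles, positions=None, pops=None, **kw):
    """Hand-built matrix helper for unit tests."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n, s = alleles.shape
    if positions is None:
        positions = np.arange(1, s + 1) * 100
    if pops is None:
        pops = ["AFR"] * n
    return HaplotypeMatrix(
        positions=np.asarray(positions, dtype=np.int64),
        alleles=alleles,
        hap_ids=[f"h{i // 2:02d}_{i % 2}" for i in range(n)],
        pop_labels=list(pops),
        **kw,
    )


def central_focal(matrix, rows=None, lo=0.2, hi=0.8):
    """Focal SNP: site nearest the locus centre with intermediate frequency."""
    center = (matrix.positions[0] + matrix.positions[-1]) / 2
    best = None
    for s in range(matrix.n_sites):
        p = matrix.derived_frequency(s, rows)
        if lo <= p <= hi:
            d = abs(matrix.positions[s] - center)
            if best is None or d < best[0]:
                best = (d, s)
    return int(matrix.positions[best[1]]) if best else None


@pytest.fixture(scope="session")
def neutral_locus():
    """One moderate neutral locus shared across tests."""
    cfg = SimulationConfig(
        seed=7, n_ref=40, n_tgt=40, locus_length=60_000,
    )
    return simulate_locus(cfg)


@pytest.fixture(scope="session")
def introgressed_locus():
    cfg = SimulationConfig(
        seed=13, n_ref=40, n_tgt=40, locus_length=60_000,
        introgression_fraction=0.05,
    )
    return simulate_locus(cfg)
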