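import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes _oracles importable

from prsbench.geno_io import GenotypeMatrix, VariantRecord
from prsbench.synthdata import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured synthetic cohort shared across tests."""
    cfg = SimulationConfig(
        n_variants=400, n_blocks=20, n_cases=150, n_controls=250, seed=11
    )
    return simulate_cohort(cfg)


@pytest.fixture
def toy_genotypes():
    """Hand-sized dosage matrix: 5 samples x 4 variants on two chromosomes."""
    variants = [
        VariantRecord("1", 1_000, "v1", "A", "G"),
        VariantRecord("1", 2_000, "v2", "C", "T"),
        VariantRecord("1", 500_000, "v3", "G", "A"),
        VariantRecord("2", 1_000, "v4", "T", "G"),
    ]
    dosage = np.array(
        [
            [0, 0, 2, 1],
            [1, 1, 1, 0],
            [2, 2, 0, 2],
            [1, 1, 2, 1],
            [0, 0, 1, 0],
        ],
        dtype=float,
    )
    return GenotypeMatrix(samples=[f"s{i}" for i in range(5)], variants=variants, dosage=dosage)


def make_genotypes(dosage, positions=None, chroms=None, prefix="v"):
    """Build a GenotypeMatrix around a plain dosage array."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    positions = positions if positions is not None else [1000 * (j + 1) for j in range(m)]
    chroms = chroms if chroms is not None else ["1"] * m
    variants = [
        VariantRecord(chroms[j], int(positions[j]), f"{prefix}{j}", "A", "G") for j in range(m)
    ]
    return GenotypeMatrix(samples=[f"s{i}" for i in range(n)], variants=variants, dosage=dosage)
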