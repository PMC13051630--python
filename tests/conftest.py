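import numpy as np
import pandas as pd
import pytest

from crosspred.genotype_core import CrossTable, GenotypeMatrix
from crosspred.simdata import SimConfig, simulate_founder_genotypes


@pytest.fixture
def tiny_panel() -> GenotypeMatrix:
    """Five inbreds at six loci, hand-written, with one heterozygous call."""
    values = np.array(
        [
            [-1, -1, 1, 1, -1, 1],
            [-1, 1, 1, -1, -1, 1],
            [1, 1, -1, -1, -1, 1],
            [1, -1, -1, 1, 0, 1],
            [-1, 1, 1, 1, -1, -1],
        ]
    )
    return GenotypeMatrix(
        [f"P{i}" for i in range(1, 6)],
        [f"{c}:{100 * (j + 1)}" for j, c in enumerate("112233")],
        values,
    )


@pytest.fixture
def small_founders() -> GenotypeMatrix:
    cfg = SimConfig(
        n_inbred=40, n_loci=120, n_parents=8, n_f1=20, seed=1234,
        maf_range=(0.15, 0.5), residual_het_rate=0.02,
    )
    return simulate_founder_genotypes(cfg)


@pytest.fixture
def simple_crosses() -> CrossTable:
    return CrossTable(
        pd.DataFrame(
            {
                "f1_id": ["F1_001", "F1_002"],
                "mother_id": ["P1", "P2"],
                "father_id": ["P2", "P3"],
            }
        )
    )
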