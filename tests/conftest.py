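import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from macrobench import io_formats
from macrobench import synthetic_fixtures as sf


@pytest.fixture
def rng():
    return np.random.default_rng(20150903)


@pytest.fixture
def curation_fixture():
    """12 ΔΔG records with 3 planted curation violations (one of them a
    replicate pair, so 4 records are rejected and 8 kept)."""
    return sf.simulate_ddg_dataset(12, target_correlation=0.7, seed=42,
                                   plant_violations=True)


@pytest.fixture
def small_msa():
    return io_formats.Msa(
        ["s1", "s2", "s3", "s4"],
        ["ACDE", "ACDF", "AGHE", "AGHF"],
    )


@pytest.fixture
def backbone_native():
    return sf.simulate_backbone_structure(30, seed=7)


@pytest.fixture
def loop_residues():
    return [("A", str(i)) for i in range(11, 19)]
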