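import numpy as np
import pandas as pd
import pytest

from uvmtk import PipelineConfig, SegmentedProfile
from uvmtk.genome import grch37_genome


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def genome():
    return grch37_genome()


@pytest.fixture()
def toy_profile():
    """One sample, two chromosomes, three segments (0-based half-open)."""
    seg = pd.DataFrame(
        {
            "chrom": ["1", "1", "2"],
            "start": [0, 50_000_000, 0],
            "end": [50_000_000, 120_000_000, 80_000_000],
            "log2": [0.4, 0.0, -0.6],
        }
    )
    return SegmentedProfile(sample="S1", segments=seg, purity=0.7)


@pytest.fixture()
def toy_genes():
    return pd.DataFrame(
        {
            "chrom": ["1", "1", "2", "3"],
            "start": [10_000_000, 45_000_000, 10_000_000, 10_000_000],
            "end": [10_100_000, 55_000_000, 10_100_000, 10_100_000],
            "gene": ["gA", "gB", "gC", "gD"],
            "arm": ["1p", "1p", "2p", "3p"],
            "max_tx_len": [2000, 3000, 1500, 1800],
        }
    )


# Independent reference routes (enumeration / step-up / projected gradient)
# live in uvmtk.validation; they never call the implementations they check.
from uvmtk.validation import (  # noqa: E402,F401
    hypergeom_enumeration_p,
    nnls_projected_gradient,
)
from uvmtk.validation import bh_stepup as bh_stepup_oracle  # noqa: E402,F401
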