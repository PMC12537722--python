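import numpy as np
import pandas as pd
import pytest

from smtz.community import CountTable
from smtz.flux import PorewaterProfile
from smtz.headspace import JarGeometry, LabConditions


@pytest.fixture
def jar() -> JarGeometry:
    """Study jar: 600 mL, 133 mL sediment, 200 mL water, 200 mL headspace."""
    return JarGeometry()


@pytest.fixture
def lab() -> LabConditions:
    return LabConditions()


@pytest.fixture
def linear_profile() -> PorewaterProfile:
    """Noiseless core: sulfate 28 mM at the seafloor, depleted at 25 cm."""
    depths = np.arange(1.0, 40.0, 2.0)
    sulfate = np.maximum(0.0, 28.0 * (1.0 - depths / 25.0))
    return PorewaterProfile(
        site="I", bay="control", season="summer",
        depths=depths, analytes={"sulfate": sulfate}, porosity=0.8,
    )


def make_count_table(counts: np.ndarray, families=None, metadata=None) -> CountTable:
    counts = np.asarray(counts)
    n, k = counts.shape
    families = families or [f"Fam{j}" for j in range(k)]
    sample_ids = [f"S{i}" for i in range(n)]
    if metadata is None:
        metadata = pd.DataFrame(
            {
                "bay": ["heated" if i % 2 else "control" for i in range(n)],
                "season": ["summer"] * n,
                "depth": [float(i) for i in range(n)],
                "site": ["x"] * n,
            },
            index=sample_ids,
        )
    taxonomy = {f: f"Archaea;P;C;O;{f}" for f in families}
    return CountTable(
        sample_ids=sample_ids, asv_ids=list(families), counts=counts,
        taxonomy=taxonomy, metadata=metadata,
    )


@pytest.fixture
def count_table() -> CountTable:
    return make_count_table(
        np.array([[5, 3, 0], [1, 1, 1], [0, 2, 8], [4, 4, 4]])
    )
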