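import numpy as np
import pandas as pd
import pytest

from camnet.design import SampleDesign
from camnet.matrix import OmicsMatrix, Stage


def make_design(groups, reps, n_qc=0, layer="protein"):
    rows = []
    for g in groups:
        for r in range(1, reps + 1):
            rows.append((f"{g}_r{r}", g, False))
    for q in range(1, n_qc + 1):
        rows.append((f"QC_{q}", "", True))
    t = pd.DataFrame(rows, columns=["sample_id", "group", "is_qc"]).set_index("sample_id")
    return SampleDesign(t, layer=layer)


def make_matrix(values, design=None, layer="protein", stage=Stage.RAW, features=None):
    """values: 2D array-like (features x samples)."""
    arr = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(arr.shape[0])]
    samples = design.sample_ids if design is not None else [f"s{j}" for j in range(arr.shape[1])]
    return OmicsMatrix(
        pd.DataFrame(arr, index=features, columns=samples), layer=layer, stage=stage
    )


@pytest.fixture
def two_group_design():
    return make_design(["A", "B"], 3)


@pytest.fixture
def metabolite_design():
    return make_design(["A", "B"], 6, n_qc=4, layer="metabolite")
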