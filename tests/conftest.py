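import numpy as np
import pandas as pd
import pytest

from soilsucc import FeatureTable, SampleFrame, TraitMatrix


@pytest.fixture
def small_counts() -> FeatureTable:
    values = pd.DataFrame(
        [[6, 10, 5], [3, 10, 0], [1, 0, 5]],
        index=["f1", "f2", "f3"], columns=["s1", "s2", "s3"],
    )
    return FeatureTable(values=values, kind="otu", marker="16S")


@pytest.fixture
def paired_frame() -> SampleFrame:
    rows = []
    for i, st in enumerate(["managed", "recent", "late"] * 3):
        rows.append({"sample_id": f"P{i}G", "pair_id": f"P{i}", "stage": st,
                     "pH": 6.2, "pair_distance_km": 2.0})
        rows.append({"sample_id": f"P{i}F", "pair_id": f"P{i}",
                     "stage": "forest", "pH": 4.5, "pair_distance_km": 2.0})
    return SampleFrame(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture
def triangle_traits() -> TraitMatrix:
    # taxa at (0,0), (0.6,0), (0.6,0.8): pairwise distances 0.6, 1.0, 0.8
    values = pd.DataFrame(
        [[0.0, 0.0], [0.6, 0.0], [0.6, 0.8]],
        index=["A", "B", "C"], columns=["g1", "g2"],
    )
    return TraitMatrix(values=values,
                       family_class={"g1": "C", "g2": "C"})


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
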