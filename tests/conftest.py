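import numpy as np
import pandas as pd
import pytest

from dockclass import CompoundRecord, ScoreTable


@pytest.fixture
def small_table() -> ScoreTable:
    """3 compounds x 3 structures with one missing entry (c2 failed in S3)."""
    frame = pd.DataFrame(
        {
            "S1": [-9.0, -8.0, -10.0],
            "S2": [-11.0, -8.5, -9.5],
            "S3": [-10.0, np.nan, -9.0],
        },
        index=["c1", "c2", "c3"],
    )
    return ScoreTable(frame)


@pytest.fixture
def labeled_records() -> list[CompoundRecord]:
    return [
        CompoundRecord("a", smiles="c1ccccc1O", pchembl_values=[9.0], activity_label=1,
                       docking_scores={"S1": -10.0}),
        CompoundRecord("b", smiles="c1ccccc1N", pchembl_values=[7.0], activity_label=0,
                       docking_scores={"S1": -8.0}),
        CompoundRecord("c", smiles="c1ccccc1C", pchembl_values=[6.5], activity_label=0,
                       docking_scores={"S1": -7.5}),
    ]
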