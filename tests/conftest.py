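import hypothesis
import pandas as pd
import pytest

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def toy_controls() -> pd.DataFrame:
    """Two control fish with two rods each: fish means 5 and 6."""
    return pd.DataFrame(
        {
            "week_id": ["W0"] * 4,
            "compound_id": ["DMSO"] * 4,
            "treatment_role": ["control"] * 4,
            "fish_id": ["A", "A", "B", "B"],
            "rod_id": ["r1", "r2", "r3", "r4"],
            "d_growth_um": [4.0, 6.0, 5.0, 7.0],
            "d_shed_um": [3.0, 3.5, 4.0, 4.5],
        }
    )
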