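import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_plate() -> pd.DataFrame:
    """Tiny hand-built screen: 4 controls, 2 pseudo-positives, 3 compounds.

    Controls: nuclei {90, 110, 95, 105} (mean 100, sd ~9.13), area x400.
    'strong' exceeds mean + 4 SD on both channels, 'nuclei_only' only on
    nuclei, 'null' sits at the control mean.
    """
    rows = []
    for i, (n, a) in enumerate(zip([90, 110, 95, 105], [36000, 44000, 38000, 42000])):
        rows.append((1, f"A{i + 1}", "control_1x", None, 0.0, n, a))
    for i, (n, a) in enumerate(zip([200, 210], [80000, 84000])):
        rows.append((1, f"B{i + 1}", "control_2x", None, 0.0, n, a))
    rows.append((1, "C1", "compound", "strong", 1.0, 160, 64000))
    rows.append((1, "C2", "compound", "nuclei_only", 1.0, 160, 40500))
    rows.append((1, "C3", "compound", "null", 1.0, 100, 40000))
    return pd.DataFrame(
        rows,
        columns=["plate_id", "well", "role", "compound_id", "conc_um",
                 "nuclei_count", "gfp_area"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
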