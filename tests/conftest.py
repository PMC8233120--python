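import numpy as np
import pandas as pd
import pytest

from netprog import (RegionAtlas, SimulationConfig, make_default_atlas,
                     normalize_cohort, simulate_cohort)


@pytest.fixture(scope="session")
def default_atlas():
    return make_default_atlas()


@pytest.fixture(scope="session")
def toy_atlas():
    """Two homotopic pairs plus the brainstem (5 regions)."""
    t = pd.DataFrame({
        "region_id": range(5),
        "name": ["hip_ant_L", "cortex_L", "hip_ant_R", "cortex_R", "brainstem"],
        "hemisphere": ["left", "left", "right", "right", "bilateral"],
        "rsn_label": [0, 1, 0, 1, 0],
        "is_anterior_hippocampus": [True, False, True, False, False],
    })
    return RegionAtlas(t)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale simulated cohort (16 controls, 8 patients)."""
    cfg = SimulationConfig(n_controls=16, n_patients=8, n_right_focus=5,
                           seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Default-size cohort (70 + 40) with no planted effect."""
    cfg = SimulationConfig(effect_profile=(0.0,) * 5, seed=1234)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_corrected(null_cohort):
    cohort, _ = null_cohort
    return normalize_cohort(cohort)
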