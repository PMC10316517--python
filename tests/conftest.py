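import numpy as np
import pandas as pd
import pytest

import aquacosm as aq


@pytest.fixture(scope="session")
def setup() -> aq.ModelSetup:
    """Default model setup shared across tests (read-only)."""
    return aq.ModelSetup()


def make_treatment(level: int, temperature: float = 22.0) -> aq.Treatment:
    return aq.Treatment(
        aro_level=level,
        temperature=temperature,
        concentrations=aq.nominal_concentrations(level),
    )


@pytest.fixture(scope="session")
def control_run(setup) -> aq.SimulationResult:
    """Control treatment, scenario A1, mixed community."""
    return aq.run_simulation("A1", 3, make_treatment(0), setup)


@pytest.fixture(scope="session")
def d2_set3_endpoints(setup) -> pd.DataFrame:
    """Endpoint table of the selected scenario over the full design."""
    return aq.run_full_design("D2", 3, setup)


# ---------------------------------------------------------------------------
# the printed set-3 correlation matrix (scenario x group x temperature)
# used as input to the selection procedure
# ---------------------------------------------------------------------------

SET3_CORRELATIONS = {
    "A1": {"phytoplankton": (0.477, 0.518), "periphyton": (0.590, 0.878),
           "macrophytes": (0.472, 0.777)},
    "A2": {"phytoplankton": (0.477, 0.544), "periphyton": (0.590, 0.779),
           "macrophytes": (0.472, 0.615)},
    "B1": {"phytoplankton": (0.507, 0.480), "periphyton": (0.592, 0.880),
           "macrophytes": (0.969, 0.579)},
    "B2": {"phytoplankton": (-0.582, 0.439), "periphyton": (0.778, 0.951),
           "macrophytes": (0.969, 0.753)},
    "C1": {"phytoplankton": (-0.365, -0.344), "periphyton": (0.861, 0.890),
           "macrophytes": (0.459, 0.767)},
    "C2": {"phytoplankton": (-0.365, 0.432), "periphyton": (0.861, 0.950),
           "macrophytes": (0.459, 0.604)},
    "D1": {"phytoplankton": (-0.414, -0.365), "periphyton": (0.850, 0.939),
           "macrophytes": (0.837, 0.849)},
    "D2": {"phytoplankton": (-0.414, 0.505), "periphyton": (0.850, 0.971),
           "macrophytes": (0.837, 0.766)},
}


def set3_correlation_entries() -> dict[str, list[aq.CorrelationEntry]]:
    """CorrelationEntry tables built from the printed set-3 r matrix,
    re-deriving p-values and tiers for 6-point curves."""
    out = {}
    for sid, groups in SET3_CORRELATIONS.items():
        entries = []
        for group, (r_cool, r_warm) in groups.items():
            entries.append(aq.CorrelationEntry.from_r(group, 22.0, r_cool, n=6))
            entries.append(aq.CorrelationEntry.from_r(group, 26.0, r_warm, n=6))
        out[sid] = entries
    return out


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
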