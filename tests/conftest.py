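import numpy as np
import pandas as pd
import pytest

from prsvar.params import SimulationParams
from prsvar.simulate import simulate_population

DOSE_SERIES = (0.6, 1.0, 2.0, 5.0, 20.0)


@pytest.fixture
def params():
    """Reference-strain parameters with dose-stable pathway noise."""
    return SimulationParams(lambda_mode="relative")


@pytest.fixture
def recovery_params():
    """Conditions with pathway variability 0.05 split 0.04 + 0.01."""
    return SimulationParams(
        eta2_L=0.04,
        eta2_lambda=0.01,
        eta2_G=0.04,
        eta2_gamma=0.005,
        lambda_mode="relative",
    )


def simulate_strain_table(
    params: SimulationParams,
    seed: int,
    strain: str,
    n_replicates: int = 3,
    n_cells: int = 200,
    doses=DOSE_SERIES,
) -> pd.DataFrame:
    """Multi-replicate dose series for one strain, one rng stream."""
    rng = np.random.default_rng(seed)
    frames = [
        simulate_population(
            params, n_cells, d, strain=strain, replicate=f"rep{r + 1}", rng=rng
        )
        for r in range(n_replicates)
        for d in doses
    ]
    return pd.concat(frames, ignore_index=True)
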