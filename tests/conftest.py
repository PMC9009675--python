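import numpy as np
import pandas as pd
import pytest

from mgidi import SimulationConfig, TraitSim, TraitSpec, TrialData, simulate_met


def make_trial(values: np.ndarray, *, e: int = 1, b: int = None, name: str = "y") -> TrialData:
    """Build a balanced TrialData from a g x (e*b) value array (one trait)."""
    values = np.asarray(values, dtype=float)
    g = values.shape[0]
    if b is None:
        b = values.shape[1] // e
    rows = []
    for i in range(g):
        for j in range(e):
            for k in range(b):
                rows.append(
                    {
                        "genotype": f"G{i + 1:02d}",
                        "environment": f"E{j + 1}",
                        "block": f"B{k + 1}",
                        name: values[i, j * b + k],
                    }
                )
    return TrialData(pd.DataFrame(rows), [TraitSpec(name)])


def one_trait_config(g=18, e=2, b=3, var_g=1.0, var_ge=0.5, var_e=1.0, mean=10.0, seed=0):
    return SimulationConfig(
        g=g, e=e, b=b,
        traits=[TraitSim("y", mean=mean, var_g=var_g, var_ge=var_ge, var_e=var_e)],
        seed=seed,
    )


@pytest.fixture(scope="session")
def wheat_sim():
    """One draw from the wheat-drought preset, shared across tests."""
    from mgidi import preset_wheat_drought

    cfg = preset_wheat_drought(seed=42)
    data, truth = simulate_met(cfg)
    return cfg, data, truth


@pytest.fixture(scope="session")
def wheat_fits(wheat_sim):
    from mgidi import fit_all_traits

    _, data, _ = wheat_sim
    return fit_all_traits(data)
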