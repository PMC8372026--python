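import numpy as np
import pandas as pd
import pytest

from rgctools import synthetic


@pytest.fixture(scope="session")
def control_population():
    """Steady-state fully cycling population, dual 1 h / 0.5 h pulse design."""
    cfg = synthetic.CycleSimConfig(
        seed=11, n_cells=30_000, t_g1=7.0, t_s=5.31, t_g2=2.0, t_m=0.83
    )
    return cfg, synthetic.simulate_population(cfg)


@pytest.fixture(scope="session")
def small_counts():
    """600-cell, 800-gene NB matrix with planted type markers."""
    cfg = synthetic.ScSimConfig(
        seed=3, n_genes=800, n_cells_per_group={"CAG": 300, "Hes5": 300}
    )
    return cfg, synthetic.simulate_counts(cfg)


@pytest.fixture(scope="session")
def planted_network():
    cfg = synthetic.RegNetSimConfig(seed=5)
    expr, truth = synthetic.simulate_regnet(cfg)
    return cfg, expr, truth


@pytest.fixture()
def mfi_records():
    rng = np.random.default_rng(0)
    rows = []
    for group, offset in (("CAG", 30.0), ("Hes5", 100.0)):
        for animal in range(4):
            n = 40
            raw = np.clip(rng.normal(offset + 20, 15, n), 0, 255)
            rows.append(
                pd.DataFrame(
                    {
                        "group": group,
                        "animal_id": f"{group}_a{animal}",
                        "raw_intensity": raw,
                        "background": rng.uniform(5, 15, n),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
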