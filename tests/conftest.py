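import numpy as np
import pandas as pd
import pytest

import dustrisk as dr

RISK_COMPOUNDS = ["DMP", "DEP", "IBP", "DBP", "BBP", "DOP"]

#: Closed-form pathway ratios implied by the adult occupational factors:
#: HQ_inh/HQ_ing = IR_inh / (PEF · IR_ing · 1e-6) and
#: HQ_der/HQ_ing = SA · AF · ABS / IR_ing.
INH_ING_RATIO = 15.7 / (1.36e9 * 50 * 1e-6)
DER_ING_RATIO = 4000 * 0.07 * 0.001 / 50


@pytest.fixture(scope="session")
def scenario():
    return dr.load_scenario(dr.packaged_scenario_path("yazd_adult"))


@pytest.fixture(scope="session")
def adult(scenario):
    return scenario.adult


@pytest.fixture(scope="session")
def fixtures():
    return {name: dr.load_fixture_table(name)
            for name in ("table3", "table4", "table5", "table6", "table7",
                         "table8")}


@pytest.fixture(scope="session")
def synth_table():
    return dr.generate_dust_dataset(seed=7)


def station_body(df: pd.DataFrame) -> pd.DataFrame:
    """The 15 station rows of a fixture table (Mean row dropped)."""
    return df[df["station"] != "Mean"].reset_index(drop=True)


def grid(df: pd.DataFrame) -> np.ndarray:
    """Station x compound value matrix of a hazard fixture table."""
    return station_body(df)[RISK_COMPOUNDS].to_numpy(float)
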