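import numpy as np
import pandas as pd
import pytest

from coralmeta import Arm, ExperimentRecord, FactorialQuad


@pytest.fixture
def warming_record():
    """The worked example: V_o=10, V_i=8 at 300 K and 302 K."""
    return ExperimentRecord(
        study_id="s1", genus="Acropora", attribute="survival",
        arm_type="warming",
        control_mean=10.0, control_sd=1.0, control_n=4,
        treatment_mean=8.0, treatment_sd=1.0, treatment_n=4,
        t_control_C=300.0 - 273.15, t_treatment_C=302.0 - 273.15,
    )


@pytest.fixture
def co2_record():
    return ExperimentRecord(
        study_id="s2", genus="Porites", attribute="calcification",
        arm_type="co2",
        control_mean=10.0, control_sd=1.0, control_n=4,
        treatment_mean=9.0, treatment_sd=1.0, treatment_n=4,
        pco2_control_uatm=400.0, pco2_treatment_uatm=800.0,
    )


@pytest.fixture
def simple_quad():
    """Four arms n=4, SD=1, means (control, warming, co2, both) = (10, 8, 9, 6)."""
    return FactorialQuad(
        study_id="f1", genus="Acropora", attribute="calcification",
        control=Arm(10.0, 1.0, 4), warming=Arm(8.0, 1.0, 4),
        co2=Arm(9.0, 1.0, 4), both=Arm(6.0, 1.0, 4),
        t_control_C=26.0, t_treatment_C=29.0,
        pco2_control_uatm=400.0, pco2_treatment_uatm=700.0,
    )


@pytest.fixture
def effects_frame():
    """A small heterogeneous effect-size table for meta-analysis tests."""
    rng = np.random.default_rng(7)
    k = 12
    return pd.DataFrame({
        "value": rng.normal(0.8, 0.3, k),
        "variance": rng.uniform(0.01, 0.05, k),
        "study_id": [f"s{i // 2}" for i in range(k)],
        "genus": [f"g{i % 3}" for i in range(k)],
    })
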