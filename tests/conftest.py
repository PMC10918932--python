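import math
from datetime import date

import pytest

from careflow.los import LosDistribution
from careflow.params import ModelParameters, RenegeConfig, ServiceParams


def single_service_params(
    arrival_rate: float,
    los: LosDistribution,
    capacity: float = math.inf,
    renege: RenegeConfig | None = None,
) -> ModelParameters:
    """A one-node system (service -> exit) for queueing-theory checks."""
    sp = ServiceParams(
        service_id="L2_GP_high",
        level=2,
        arrival_rate=arrival_rate,
        los=los,
        transitions={"exit": 1.0},
        capacity=capacity,
        renege=renege,
    )
    return ModelParameters({"L2_GP_high": sp})


def two_service_params(p_forward: float = 0.3, **kwargs) -> ModelParameters:
    """GP feeding IAPT therapy with probability ``p_forward``."""
    a = ServiceParams(
        service_id="L2_GP_high",
        level=2,
        arrival_rate=kwargs.get("arrival_rate", 5.0),
        los=LosDistribution("fixed", {"days": 3}),
        transitions={"L3_IAPT_therapy": p_forward, "exit": 1.0 - p_forward},
    )
    b = ServiceParams(
        service_id="L3_IAPT_therapy",
        level=3,
        arrival_rate=0.0,
        los=LosDistribution("fixed", {"days": 5}),
        transitions={"exit": 1.0},
    )
    return ModelParameters({"L2_GP_high": a, "L3_IAPT_therapy": b})


@pytest.fixture
def start() -> date:
    return date(2019, 4, 1)
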