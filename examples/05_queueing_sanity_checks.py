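"""Check the simulator against closed-form queueing theory.

Two classical limits: an infinite-server system whose mean occupancy must
approach arrival rate x mean stay (Little's law), and an M/M/c system
whose mean queue length must approach the Erlang-C value.  The M/M/c
check runs the daily-step engine with the mean stay expressed as 100
steps, so the discrete chain approximates the continuous queue.
"""

from datetime import date

import numpy as np

from careflow import LosDistribution, ModelParameters, ServiceParams, run_replication


def one_service(lam, los, capacity=float("inf")):
    sp = ServiceParams(
        service_id="L2_GP_high",
        level=2,
        arrival_rate=lam,
        los=los,
        transitions={"exit": 1.0},
        capacity=capacity,
    )
    return ModelParameters({"L2_GP_high": sp})


def erlang_c_queue_length(c, a):
    b = 1.0
    for k in range(1, c + 1):
        b = a * b / (k + a * b)
    rho = a / c
    return (b / (1 - rho * (1 - b))) * rho / (1 - rho)


start = date(2019, 4, 1)

params = one_service(5.0, LosDistribution("fixed", {"days": 4}))
res = run_replication(params, start_date=start, horizon_days=10_000, seed=1)
occ = res.occupancy[0, 30:].mean()
print(f"M/G/inf occupancy: simulated {occ:.2f} vs Little's law 20.00")

m, c, offered = 100, 6, 4.0
params = one_service(offered / m, LosDistribution("geometric", {"mean": m}), capacity=c)
values = [
    run_replication(params, start_date=start, horizon_days=1_000_000, seed=s)
    .queue_size[0, 500:]
    .mean()
    for s in (1, 2, 3)
]
target = erlang_c_queue_length(c, offered)
print(f"M/M/c queue length: simulated {np.mean(values):.3f} vs Erlang-C {target:.3f}")
# Agreement within a few percent confirms the daily event loop (arrivals,
# completions, admissions) reproduces the continuous-time queueing limits.
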