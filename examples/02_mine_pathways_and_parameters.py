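"""Mine an event log back into pathways, a transition network and
simulator parameters, and check the estimates against the generator.

Because generation is capacity-free, the mined arrival rates and
transition probabilities are unconfounded by queueing and should sit
within sampling error of the ground truth.
"""

from datetime import date

from careflow import (
    SyntheticCohortSpec,
    build_pathway_graph,
    estimate_parameters,
    generate_event_log,
    reconstruct_pathways,
)

spec = SyntheticCohortSpec(start=date(2019, 4, 1), end=date(2021, 4, 1), seed=42)
log = generate_event_log(spec)
sequences = reconstruct_pathways(log)
graph = build_pathway_graph(sequences)
estimates = estimate_parameters(sequences, horizon_days=spec.horizon_days)

print(f"pathways mined: {len(sequences):,}; transitions: {graph.total_transitions:,}")
print("\nbusiest routes (top 5 by relative frequency):")
edges = graph.edge_frame().sort_values("rel_freq_pct", ascending=False).head(5)
print(edges.to_string(index=False))

print("\nmined vs ground-truth arrival rates (per day):")
for sid in ("L2_GP_high", "L2_GP_low"):
    true = spec.ground_truth.services[sid].arrival_rate
    print(f"  {sid:12s} mined {estimates.arrival_rate[sid]:.2f} vs true {true:.2f}")

row = estimates.transition_probs.loc["L2_GP_high"]
print("\nGP high-intensity routing (mined | true):")
for dest, p in spec.ground_truth.services["L2_GP_high"].transitions.items():
    print(f"  -> {dest:20s} {row[dest]:.3f} | {p:.3f}")
# Each mined probability should differ from truth only by binomial noise.
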