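"""Simulate a qPCR panel with planted network rewiring.

Builds ground-truth co-expression graphs for three developmental stages plus
a perturbation condition that reverts the network to its immature (first
stage) configuration, samples expression from the matching Gaussian
graphical models, and encodes it as OpenArray-style Ct values with
undetermined/flagged entries.
"""

from climenet import synthdata

truth = synthdata.gen_stage_truth(
    n_genes=30, stages=["PND14", "PND21", "PND28"], n_rewire=5, seed=7
)
synthdata.add_reversion_condition(truth, seed=8)

for label in truth.labels:
    g = truth.stage_graphs[label]
    print(f"{label:>10}: {g.number_of_edges()} edges "
          f"({truth.condition_of(label)})")
print("planned losers :", ", ".join(truth.planned_losers))
print("planned gainers:", ", ".join(truth.planned_gainers))

expr = synthdata.simulate_expression(truth, n_per_stage=12, noise_sd=0.1, seed=9)
ct = synthdata.encode_ct(expr, flag_rate=0.02, noise_sd=0.1, seed=10)
bad = (ct.status != "ok").values.mean()
print(f"expression: {expr.n_genes} genes x {expr.n_samples} samples")
print(f"Ct table  : {bad:.1%} undetermined/flagged entries")
# The planned losers hold edges at PND14 that are gone by PND28, and the
# perturbed condition restores the PND14 wiring - the structure the
# connectivity analysis should recover.
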