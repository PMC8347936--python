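"""Call bound promoters on a small simulated ChIP tiling array.

Generates a 200-promoter array with a quarter of the promoters carrying a
spiked enrichment region, averages the two ChIP replicates per probe, and
runs the 5-probe moving-window one-sided t-test (alpha = 0.0017 per window,
family-wise ~0.05 per promoter).
"""

from promtarget import (
    SimulationConfig,
    adjusted_alpha,
    call_bound_all,
    generate_array_design,
    generate_chip_signal,
    sample_truth,
)

cfg = SimulationConfig(seed=0, n_seq_ids=200)
design, annotation = generate_array_design(cfg)
truth = sample_truth(design, annotation, cfg)
signal = generate_chip_signal(design, truth, cfg)

windows, calls = call_bound_all(design, signal)
called = set(calls.loc[calls["bound"], "seq_id"])
hit = len(called & truth.bound_seq_ids)

print(f"family-wise alpha over 30 windows: {adjusted_alpha(0.0017, 30):.4f}")
print(f"sequence IDs: {len(calls)}, windows tested: {len(windows)}")
print(f"called bound: {len(called)} (truth: {len(truth.bound_seq_ids)}, recovered: {hit})")
print(f"median effect size of bound calls (log2): "
      f"{calls.loc[calls['bound'], 'effect_size'].median():.2f}")
# The effect size is the maximum 5-probe window mean; values above 0.25
# (a 1.2-fold enrichment) pass the downstream binding filter.
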