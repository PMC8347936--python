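"""Differential expression between WT and knockout replicate groups.

Simulates log2 expression for ~200 genes (1-3 probe sets each, four WT and
four KO samples), runs the pooled two-sample t-test per probe set, removes
genes whose significant probe sets disagree in sign, and calls a gene
differential when any probe set reaches p < 0.05.
"""

from promtarget import (
    SimulationConfig,
    generate_array_design,
    generate_expression,
    profile_expression,
    sample_truth,
)

cfg = SimulationConfig(seed=0, n_seq_ids=200, n_ambiguous=2)
design, annotation = generate_array_design(cfg)
truth = sample_truth(design, annotation, cfg)
matrix = generate_expression(annotation, truth, cfg)

result = profile_expression(matrix)
de = result.de_genes

print(f"probe sets tested: {len(result.probe_table)}")
print(f"significant probe sets (p < 0.05): {result.n_significant_probe_sets}")
print(f"genes removed as ambiguous: {len(result.removed_genes)} "
      f"(injected: {truth.ambiguous})")
print(f"DE genes: {len(de)} of {len(result.gene_table)} "
      f"({int((de['direction'] > 0).sum())} higher in WT, "
      f"{int((de['direction'] < 0).sum())} higher in KO)")
example = de.iloc[0]
print(f"example: {de.index[0]} effect {example['effect']:+.3f} log2 "
      f"= {2**abs(example['effect']):.1f}-fold, direction {example['direction']:+d}")
# A positive effect (WT - KO) means the factor normally activates the gene;
# the fold change is 2**|effect|.
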