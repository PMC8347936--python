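"""Integrate binding and expression evidence into a target-gene list.

Runs both platforms on one simulated dataset, matches them by gene symbol,
applies the effect-size filters (binding > 0.25, |expression| > 0.5 on the
log2 scale, i.e. 1.2-fold enrichment and 1.4-fold change) and splits the
targets into activated and repressed classes.
"""

from promtarget import (
    SimulationConfig,
    assign_genes_all,
    call_bound_all,
    filter_targets,
    fisher_enrichment,
    generate_array_design,
    generate_chip_signal,
    generate_expression,
    match_platforms,
    overlap_stats,
    profile_expression,
    sample_truth,
)

cfg = SimulationConfig(seed=0, n_seq_ids=400)
design, annotation = generate_array_design(cfg)
truth = sample_truth(design, annotation, cfg)
signal = generate_chip_signal(design, truth, cfg)
matrix = generate_expression(annotation, truth, cfg)

de = profile_expression(matrix)
_, calls = call_bound_all(design, signal)
assignment = assign_genes_all(design, annotation)

matched, n_pairs = match_platforms(de.gene_table, calls, assignment)
targets = filter_targets(matched)
n_act = int((targets["regulation"] == "activated").sum())
n_rep = int((targets["regulation"] == "repressed").sum())

print(f"matched genes (DE and bound): {len(matched)}; "
      f"(seq ID, probe set) pairs: {n_pairs}")
print(f"filtered targets: {len(targets)} = {n_act} activated + {n_rep} repressed")

# overlap of the target list with the true joint spikes
gene_of_seq = design.probes.set_index("seq_id")["gene_symbol"].to_dict()
bound_genes = {gene_of_seq[s] for s in truth.bound_seq_ids if gene_of_seq[s]}
joint = bound_genes & set(truth.de_genes)
rep = overlap_stats(set(targets["gene"]), joint, denominator=len(joint))
print(f"targets overlapping the jointly spiked truth: "
      f"{rep.intersections['A&B']} / {len(joint)} "
      f"({rep.percentages['A&B']}% of truth)")

# generic right-tailed enrichment of the target list in the truth category
universe = set(annotation["gene"])
enr = fisher_enrichment(set(targets["gene"]), {"jointly_spiked": joint}, universe)
print(f"hypergeometric right-tail p for that overlap: {enr.loc[0, 'p']:.3g}")
# A tiny p confirms the list is dominated by genuinely spiked genes.
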