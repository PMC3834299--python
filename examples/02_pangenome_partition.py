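"""Partition a called presence matrix into core / variable / reference-specific.

Prints the headline pan-genome counts and the per-strain gene-content
dissimilarity versus the sequenced reference.
"""

from genomotyper import SimulationConfig, partition, simulate_experiment
from genomotyper.calling import call_presence, fit_all_strains
from genomotyper.preprocess import average_replicates, filter_selfself_background

cfg = SimulationConfig(seed=1)
truth, arrays = simulate_experiment(cfg)
qc = filter_selfself_background(arrays.selfself)
rm = average_replicates(arrays.tensor.subset_probes(qc.kept))
P = call_presence(fit_all_strains(rm), rm)

pan = partition(P)          # core over the conspecific strains, outgroup excluded
print(f"kept probes:        {len(P.probe_ids)}")
print(f"core genes:         {len(pan.core_genes)}")
print(f"variable genes:     {len(pan.variable_genes)}")
print(f"reference-specific: {len(pan.reference_specific)}")

print("\ndissimilarity vs reference (% of reference-present genes missing):")
for s, d in pan.dissimilarity_pct.sort_values().items():
    print(f"  {s:5s} {d:5.1f}%")

# Core genes are called present in every conspecific strain; the variable
# genome is the complement. Reference-specific genes hybridize only in the
# reference — candidate strain-private gene models. The outgroup's much
# larger dissimilarity reflects genus-level divergence.
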