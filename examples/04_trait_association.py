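"""Screen for genes whose presence pattern matches a phenotype split.

Runs the full chain on simulated data with 20 planted trait genes, then
filters for genes present in phenotype group A and absent in group B,
tolerating one false negative or one false positive.  Also shows the
packaged phenotype fixtures (coccolith status; virus-lysis matrix).
"""

from genomotyper import (AssociationRule, SimulationConfig, load_trait_fixture,
                         recover_planted_traits, simulate_experiment)
from genomotyper.association import hits_to_frame

cfg = SimulationConfig(seed=1)          # 20 planted trait genes, 7/8 split
truth, arrays = simulate_experiment(cfg)

res = recover_planted_traits(truth, arrays, rule=AssociationRule(1, 1, 1))
print(f"planted trait genes : {len(res.planted)}")
print(f"recovered           : {len(res.recovered)}  "
      f"(sensitivity {res.sensitivity:.2f})")
print(f"false hits          : {res.n_false_hits} "
      f"(of which {len(set(res.false_hits) & set(res.truth_matched))} match the "
      "split in the true gene content, i.e. are not caller errors)")
print("\nfirst hits:")
print(hits_to_frame(res.hits).head(6).to_string(index=False))

# The packaged fixtures transcribe the published strain phenotype tables:
cocc = load_trait_fixture("coccoliths")
virus = load_trait_fixture("virus_susceptibility", min_lysed=1)
print(f"\ncoccolith fixture: {len(cocc.group('A'))} calcifying / "
      f"{len(cocc.group('B'))} non-calcifying strains")
print(f"virus fixture (>=1 lysis): {len(virus.group('A'))} susceptible / "
      f"{len(virus.group('B'))} resistant strains")

# fn counts group-A strains lacking the gene, fp group-B strains carrying
# it; the default rule accepts fn+fp <= 1, the published one-mismatch
# relaxation of the perfect present/absent split.
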