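"""Generate a synthetic regional aging time course with planted ground truth.

Two brain regions (HC = vulnerable hippocampus, OCC = resistant occipital
cortex), three age groups, three technical replicates per pooled sample.
"""

from synaptage import SimConfig, simulate_dataset

cfg = SimConfig(n_proteins=200, n_candidates=10, effect_fc=1.5, replicate_cv=0.10, seed=1)
table, truth = simulate_dataset(cfg)

print(f"table: {table.values.shape[0]} proteins x {table.values.shape[1]} samples")
print(f"regions: {table.regions}, ages: {list(table.age_order)}")
print(f"planted candidates: {truth.candidates()[:5]} ... ({len(truth.candidates())} total)")
hc_classes = truth.classes("HC")
first = table.protein_ids[0]
print(f"{first}: HC class {hc_classes[first].value}, "
      f"HC young replicates {table.replicate_values('HC', 'young').loc[first].round(1).tolist()}")
# The replicate values scatter around a per-(region, age) expected mean with
# ~10% multiplicative noise; candidates split between regions only at old age.
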