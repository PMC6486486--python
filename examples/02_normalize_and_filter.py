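"""Arc-Sinh normalization and the differential filtering gates.

Keeps proteins with ANOVA p <= 0.05, max fold change >= 1.2, post-hoc power
>= 0.8 and at least 2 unique peptides — the proteins with the largest
reliable changes over the aging time course.
"""

from synaptage import FilterParams, SimConfig, anova_by_age, apply_filters, arcsinh_normalize, simulate_dataset

table, truth = simulate_dataset(SimConfig(n_proteins=300, n_candidates=10, seed=2))
table = arcsinh_normalize(table)

stats = anova_by_age(table, "HC")
kept, dropped = apply_filters(stats, FilterParams())
print(f"HC: kept {len(kept)} of {len(stats)} proteins")

example = kept[0]
print(f"{example.protein}: F={example.f_statistic:.1f} p={example.p_value:.2e} "
      f"power={example.power:.3f} maxFC={example.max_fc:.2f}")
gates = {}
for st in dropped:
    for g in st.gates_failed:
        gates[g] = gates.get(g, 0) + 1
print(f"failed-gate counts among dropped: {gates}")
# Flat proteins fail mostly on p/power/fold-change together; the kept set is
# dominated by the planted changing classes plus the divergence candidates.
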