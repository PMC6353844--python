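"""Infer functional effects from mutations/CNA and personalize the model.

Synthetic mutation and copy-number records are resolved through the
inference cascade (truncating -> LOF; known variants; gene roles;
GISTIC +/-2), then combined with normalized RNA into one personalized
simulation per patient: confident discrete effects freeze nodes (strict
node variants) while continuous values retune transition rates (soft node
variants, k_up = 100^(2(norm-0.5))).
"""

import pandas as pd

from logiprofile import (
    STRATEGIES,
    CohortData,
    build_discrete_profile,
    generate_genomic_profiles,
    mini_cancer_model,
    mini_model_mapping,
    personalize_cohort,
    profile_to_frame,
)

model, base = mini_cancer_model()

mutations, cnas, kb, truth = generate_genomic_profiles(n_samples=12, seed=5)
profiles = build_discrete_profile(mutations, cnas, kb)
frame = profile_to_frame(profiles)
print(f"inferred {len(frame)} functional effects across "
      f"{frame['sample'].nunique()} samples:")
print(frame.head(6).to_string(index=False))

# keep only mutation-derived effects for the strict channel of case5
mut_profiles = {
    s: {g: e for g, e in effs.items() if e.data_type == "mutation"}
    for s, effs in profiles.items()
}

# fabricate a normalized RNA matrix for the same patients
patients = sorted(profiles)
rna = pd.DataFrame(
    {p: {"AKT1": 0.9, "AKT2": 0.7, "CCND1": 0.2} for p in patients}
)

data = CohortData(
    mutations=mut_profiles,
    rna=rna,
    mutation_samples=patients,
)
settings_map = personalize_cohort(model, base, data, STRATEGIES["case5"],
                                  mini_model_mapping())
print(f"\npersonalized {len(settings_map)} patients with strategy case5 "
      f"(mutations strict, RNA soft)")

patient = patients[0]
s = settings_map[patient]
print(f"\nsettings for {patient} (generic value: istate 0.5, rates 1.0):")
for node in model.nodes:
    ns = s.node_settings[node]
    bs = base.node_settings[node]
    if (ns.initial_prob, ns.k_up, ns.k_down) != (
        bs.initial_prob, bs.k_up, bs.k_down
    ):
        print(f"  {node:10s} istate={ns.initial_prob:.2f} "
              f"k_up={ns.k_up:.4g} k_down={ns.k_down:.4g}")
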