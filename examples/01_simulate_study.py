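"""Simulate a two-condition time-course study with planted modules.

Builds a matched pair of gene x sample log-ratio matrices (a perturbed
"test" condition and a control "reference" condition) with three planted
co-expression modules — preserved, weakly preserved and test-only — plus
independent background genes, then prints how strongly each planted block
is co-expressed in each condition.
"""

import numpy as np

import coexnet as cx

config = cx.SimulationConfig(
    modules=(
        cx.ModuleSpec("preserved_mod", 40, 0.7, 0.95, "preserved", eigenprofile_seed=1),
        cx.ModuleSpec("weak_mod", 35, 0.7, 0.95, "weak", eigenprofile_seed=2),
        cx.ModuleSpec("testonly_mod", 30, 0.7, 0.95, "specific_to_test", eigenprofile_seed=3),
    ),
    n_background_genes=120,
    noise_sd=0.3,
    rng_seed=1,
)
study = cx.simulate_two_condition_dataset(config)

print(f"genes: {len(study.gene_ids)}, samples per condition: {study.test.shape[1]}")
print(f"stages: {study.samples['stage'].value_counts().to_dict()}")
print()
print(f"{'module':>14}  {'|r| in test':>11}  {'|r| in reference':>16}")
for label in ("preserved_mod", "weak_mod", "testonly_mod", "background"):
    rows_t = study.test.loc[study.truth_labels == label].to_numpy()
    rows_r = study.reference.loc[study.truth_labels == label].to_numpy()
    iu = np.triu_indices(rows_t.shape[0], 1)
    mt = np.abs(np.corrcoef(rows_t)[iu]).mean()
    mr = np.abs(np.corrcoef(rows_r)[iu]).mean()
    print(f"{label:>14}  {mt:11.3f}  {mr:16.3f}")

# The preserved module is tightly co-expressed in both conditions, the weak
# module loses roughly half its loading in the reference, and the test-only
# module is indistinguishable from background noise there (~0.17 is the
# expected mean |r| of independent genes at 24 samples).
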