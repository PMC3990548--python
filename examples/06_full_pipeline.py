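"""Run the complete analysis end to end and inspect the run directory.

Simulate -> gene filter -> most-connected selection -> per-condition
networks -> module detection -> preservation -> stage-wise preservation ->
gene significance -> hubs -> exports, all driven by one seeded
configuration.  Rerunning the same configuration reproduces every output
byte for byte.
"""

import json
import warnings
from pathlib import Path

import coexnet as cx

config = cx.PipelineConfig(
    simulation=cx.SimulationConfig(
        modules=(
            cx.ModuleSpec("p1", 35, 0.7, 0.95, "preserved", 21),
            cx.ModuleSpec("p2", 35, 0.7, 0.95, "preserved", 22),
            cx.ModuleSpec("w1", 30, 0.7, 0.95, "weak", 23),
            cx.ModuleSpec("s1", 30, 0.7, 0.95, "specific_to_test", 24),
        ),
        n_background_genes=120,
        noise_sd=0.3,
        rng_seed=0,
    ),
    n_perm=200,
    seed=0,
)

out = Path("scratch/example_run")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    cx.run_pipeline(config, out)

manifest = json.loads((out / "run_manifest.json").read_text())
print(f"analysed {manifest['n_genes_analysed']} genes "
      f"at soft power {manifest['parameters']['soft_power_used']}")
print(f"modules: {manifest['module_sizes']}")
print("\npreservation of each detected module in the reference network:")
for module, entry in manifest["preservation"].items():
    flag = "  <- condition-specific" if entry["specific"] else ""
    print(f"  {module:>10}: Zsummary {entry['Zsummary']:8.2f}  ({entry['class']}){flag}")
print(f"\nall outputs in {out}/: {', '.join(manifest['outputs'])}")

# The two preserved modules show strong evidence (Zsummary > 10).  The
# test-only module shows none (< 2) and is flagged condition-specific — the
# signature of a perturbation-driven module; the half-loading "weak" module,
# diluted by the background genes detection absorbed, can land there too.
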