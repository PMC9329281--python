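"""Run the whole pipeline end to end and inspect the run manifest.

Equivalent shell command:  heart-age run --n-women 1500 --n-men 1500 --seed 3
"""

import json

from heartage import GeneratorConfig, RunConfig, run_pipeline

config = RunConfig(
    outdir="scratch_example_run",
    seed=3,
    generator=GeneratorConfig(
        n_women=1500, n_men=1500,
        planted_exposure_effects={"bio_000": 0.3},
    ),
)
manifest = run_pipeline(config)

print("row counts:", json.dumps(manifest["counts"]))
for sex, m in manifest["metrics"].items():
    print(f"{sex}: MAE {m['mae_uncorrected']:.2f} y, "
          f"R^2 {m['r_squared_uncorrected']:.2f}, "
          f"corrected r(delta, age) {m['r_delta_actual']:+.3f}")
print("outputs:", ", ".join(manifest["outputs"]))
# heart_age.csv holds per-participant fold, prediction, CPHA and delta;
# feature_profile.csv and phewas.csv hold the ranked association tables.
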