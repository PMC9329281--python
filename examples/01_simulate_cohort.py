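"""Generate a synthetic imaging cohort with known ground truth.

Each participant carries a latent aging offset delta (years); radiomics
features load on biological age (chronological age + delta) and on body
size, with shared low-rank noise inducing the intercorrelation real
radiomics matrices show.
"""

from heartage import GeneratorConfig, generate_cohort

config = GeneratorConfig(
    n_women=2000,
    n_men=2000,
    seed=7,
    planted_exposure_effects={"bio_000": 0.3},  # one exposure tied to aging rate
)
bundle = generate_cohort(config)

print(f"cohort: {len(bundle.cohort)} participants "
      f"({(bundle.cohort.data.sex == 'female').sum()} women)")
print(f"features: {bundle.features.shape[1]} radiomics columns "
      f"({bundle.manifest.category_counts()})")
print(f"exposures: {bundle.exposures.shape[1]} variables in "
      f"{bundle.catalogue.table.category.nunique()} categories")
print(f"latent aging offset sd: {bundle.truth.delta_true.std():.2f} years")
# The truth sidecar (delta_true, loadings, planted ids) is for validation
# only; no pipeline stage ever reads it.
bundle.save("scratch_example_cohort")
print("tables written to scratch_example_cohort/")
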