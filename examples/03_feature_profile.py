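"""Profile which radiomics features track biological heart age.

Each feature is residualized for height, weight and age, then correlated
with the corrected predicted heart age; p-values carry a Bonferroni factor
equal to the number of features tested, and features are ranked "most
informative first" (ascending corrected p, ties by |r|).
"""

from heartage import (
    GeneratorConfig, generate_cohort, profile_feature_age, run_cv, split_by_sex,
)

bundle = generate_cohort(GeneratorConfig(n_women=5000, n_men=0, seed=11))
stratum = split_by_sex(bundle.cohort)["female"]
result = run_cv(stratum, bundle.features.loc[stratum.ids], k=10, seed=1)

profile = profile_feature_age(
    bundle.features.loc[stratum.ids],
    result.cpha.to_numpy(),
    stratum.confounds(["height", "weight", "age"]),
    manifest=bundle.manifest,
).table

print(profile.head(5)[["variable_id", "category", "r", "p_corrected", "rank"]]
      .to_string(index=False))
n_sig = int(profile["significant"].sum())
print(f"{n_sig}/{len(profile)} features significant after Bonferroni x{len(profile)}")
# Top-ranked rows are the features whose age-orthogonal variation tracks
# the heart-age estimate most strongly.
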