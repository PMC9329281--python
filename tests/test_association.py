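"""Association engines: Pearson oracle values, Bonferroni families,
feature profiling and the exposure-wide scan."""

import numpy as np
import pandas as pd
import pytest

from heartage import (
    GeneratorConfig,
    bonferroni,
    default_catalogue,
    generate_cohort,
    pearson_with_p,
    phewas,
    profile_feature_age,
    split_by_sex,
)
from heartage.association import ExposureCatalogue
from heartage.cohort import SchemaError


class TestPearson:
    def test_perfect_anticorrelation(self):
        r, p = pearson_with_p([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_hand_product_moment(self):
        """dev products sum to 4.0 over sd^2 sums of 5 each -> r = 0.8."""
        r, _ = pearson_with_p([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8, abs=1e-12)

    def test_self_correlation_floors_p(self):
        x = np.arange(10.0)
        r, p = pearson_with_p(x, x)
        assert r == pytest.approx(1.0)
        assert 0 < p < 1e-50  # at or near the numerical floor, never zero

    def test_constant_vector_flagged(self):
        r, p = pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r) and np.isnan(p)

    def test_pairwise_complete_case(self):
        r, _ = pearson_with_p([1, 2, 3, 4, np.nan], [1, 3, 2, 4, 100.0])
        assert r == pytest.approx(0.8)


class TestBonferroni:
    def test_abdominal_mri_multiplier(self):
        assert bonferroni(0.001, 16) == pytest.approx(0.016)

    def test_capped_at_one(self):
        assert bonferroni(0.2, 254) == 1.0

    def test_boundary_not_significant_at_strict_inequality(self):
        p = bonferroni(0.05 / 254, 254)
        assert p == pytest.approx(0.05)
        assert not (p < 0.05)

    def test_invalid_family_size(self):
        with pytest.raises(ValueError):
            bonferroni(0.01, 0)


class TestCatalogue:
    def test_default_totals(self):
        cat = default_catalogue()
        assert len(cat) == 701
        app = cat.table["sex_applicability"].value_counts()
        assert app["both"] == 666 and app["female"] == 30 and app["male"] == 5
        assert cat.table["category"].nunique() == 13

    def test_abdominal_mri_family_size(self):
        cat = default_catalogue()
        assert cat.category_sizes("female")["Abdominal MRI"] == 16
        assert cat.category_sizes("male")["Abdominal MRI"] == 16

    def test_sex_filtering(self):
        cat = default_catalogue()
        assert len(cat.for_sex("female")) == 696
        assert len(cat.for_sex("male")) == 671

    def test_duplicate_variable_rejected(self):
        tab = default_catalogue().table.copy()
        tab.loc[1, "variable_id"] = tab.loc[0, "variable_id"]
        with pytest.raises(SchemaError):
            ExposureCatalogue(tab)


def _profile_inputs(n=2000, p=20, n_signal=5, seed=0):
    """Features where exactly n_signal columns carry the latent delta."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(45, 82, size=n)
    delta = rng.normal(scale=5.0, size=n)
    X = rng.normal(size=(n, p))
    X[:, :n_signal] += 0.15 * delta[:, None]
    features = pd.DataFrame(X, columns=[f"f{i:02d}" for i in range(p)])
    heart_age = age + delta
    confounds = pd.DataFrame(
        {
            "height": rng.normal(165, 6, size=n),
            "weight": rng.normal(70, 12, size=n),
            "age": age,
        }
    )
    return features, heart_age, confounds


class TestProfileFeatureAge:
    def test_planted_features_occupy_top_ranks(self):
        features, heart_age, confounds = _profile_inputs()
        res = profile_feature_age(features, heart_age, confounds).table
        top = set(res.loc[res["rank"] <= 5, "variable_id"])
        assert top == {f"f{i:02d}" for i in range(5)}
        assert res.loc[res["rank"] <= 5, "significant"].all()
        assert (res["m"] == 20).all()

    def test_null_heart_age_finds_nothing(self):
        features, _, confounds = _profile_inputs(seed=1)
        rng = np.random.default_rng(99)
        res = profile_feature_age(
            features, rng.normal(size=len(features)), confounds
        ).table
        assert res["significant"].sum() <= 1

    def test_single_feature_family_uncorrected(self):
        features, heart_age, confounds = _profile_inputs(p=1, n_signal=1)
        res = profile_feature_age(features, heart_age, confounds).table
        assert res["p_corrected"].iloc[0] == pytest.approx(
            res["p_raw"].iloc[0]
        )

    def test_ranking_is_total_order_on_corrected_p(self):
        features, heart_age, confounds = _profile_inputs(seed=2)
        res = profile_feature_age(features, heart_age, confounds).table
        assert sorted(res["rank"]) == list(range(1, len(res) + 1))
        assert res.sort_values("rank")["p_corrected"].is_monotonic_increasing

    def test_manifest_categories_carried(self, small_bundle):
        stratum = split_by_sex(small_bundle.cohort)["female"]
        feats = small_bundle.features.loc[stratum.ids]
        res = profile_feature_age(
            feats,
            stratum.age,
            stratum.confounds(["height", "weight", "age"]),
            manifest=small_bundle.manifest,
        ).table
        assert set(res["category"]) <= {"shape", "first_order", "texture"}


@pytest.fixture(scope="module")
def planted_scan():
    cat = default_catalogue(
        {"Abdominal MRI": 5, "Blood biomarkers": 20, "Physical measures": 15}
    )
    cfg = GeneratorConfig(
        n_women=2500,
        n_men=0,
        n_features=10,
        seed=31,
        catalogue=cat,
        planted_exposure_effects={"bio_000": 0.3, "pm_000": -0.25},
    )
    return generate_cohort(cfg), cat


class TestPhewas:
    def test_planted_exposures_detected_with_attenuated_r(self, planted_scan):
        bundle, cat = planted_scan
        stratum = split_by_sex(bundle.cohort)["female"]
        # use the true latent delta as the outcome's noisy estimate
        delta_hat = bundle.truth.delta_true.to_numpy() + np.random.default_rng(
            5
        ).normal(scale=3.0, size=len(stratum))
        res = phewas(
            delta_hat,
            bundle.exposures,
            cat,
            stratum.confounds(["height", "weight", "age"]),
            sex="female",
        ).table
        attenuation = np.corrcoef(
            delta_hat, bundle.truth.delta_true.to_numpy()
        )[0, 1]
        top = res.set_index("variable_id")
        assert top.loc["bio_000", "significant"]
        assert top.loc["pm_000", "significant"]
        assert top.loc["bio_000", "r"] == pytest.approx(
            0.3 * attenuation, abs=0.05
        )
        assert top.loc["pm_000", "r"] == pytest.approx(
            -0.25 * attenuation, abs=0.05
        )

    def test_family_sizes_are_per_category(self, planted_scan):
        bundle, cat = planted_scan
        stratum = split_by_sex(bundle.cohort)["female"]
        res = phewas(
            bundle.truth.delta_true.to_numpy(),
            bundle.exposures,
            cat,
            stratum.confounds(["height", "weight", "age"]),
            sex="female",
        ).table
        sizes = res.groupby("category")["m"].first().to_dict()
        assert sizes == {
            "Abdominal MRI": 5,
            "Blood biomarkers": 20,
            "Physical measures": 15,
        }

    def test_male_specific_absent_from_female_scan(self):
        cfg = GeneratorConfig(n_women=120, n_men=120, n_features=5, seed=32)
        bundle = generate_cohort(cfg)
        stratum = split_by_sex(bundle.cohort)["female"]
        res = phewas(
            np.zeros(len(stratum)) + np.random.default_rng(0).normal(size=len(stratum)),
            bundle.exposures.loc[stratum.ids],
            bundle.catalogue,
            stratum.confounds(["height", "weight", "age"]),
            sex="female",
            min_n=50,
        ).table
        male_vars = bundle.catalogue.table.query("sex_applicability=='male'")[
            "variable_id"
        ]
        assert not res["variable_id"].isin(male_vars).any()
        female_vars = bundle.catalogue.table.query("sex_applicability=='female'")[
            "variable_id"
        ]
        assert res["variable_id"].isin(female_vars).sum() == len(female_vars)

    def test_below_minimum_n_flagged_not_dropped(self, planted_scan):
        bundle, cat = planted_scan
        stratum = split_by_sex(bundle.cohort)["female"]
        exposures = bundle.exposures.copy()
        exposures.iloc[60:, exposures.columns.get_loc("bio_001")] = np.nan
        res = phewas(
            bundle.truth.delta_true.to_numpy(),
            exposures,
            cat,
            stratum.confounds(["height", "weight", "age"]),
            sex="female",
        ).table
        row = res.set_index("variable_id").loc["bio_001"]
        assert row["n_used"] == 60
        assert np.isnan(row["r"]) and not row["significant"]
        assert row["rank"] == len(res)  # sorts to the bottom

    def test_capping_never_changes_significance(self, planted_scan):
        bundle, cat = planted_scan
        stratum = split_by_sex(bundle.cohort)["female"]
        res = phewas(
            bundle.truth.delta_true.to_numpy(),
            bundle.exposures,
            cat,
            stratum.confounds(["height", "weight", "age"]),
            sex="female",
        ).table
        capped = res["p_corrected"] == 1.0
        assert not res.loc[capped, "significant"].any()
        assert (res.loc[capped, "neg_log10_p"] == 0.0).all()
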