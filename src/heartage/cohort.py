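"""Cohort data model: validation, exclusion filtering, sex stratification,
and the radiomics feature manifest.

The cohort is a per-participant table of demographics and confounds
(age at imaging in years, height in cm, weight in kg) with two inclusion
flags: prevalent cardiovascular disease and White ethnicity. The feature
manifest describes a 254-column radiomics matrix — 78 shape features
spanning the left ventricle (LV), right ventricle (RV) and LV myocardium
(MYO), plus 35 first-order and 141 texture features from the myocardium
only (signal-intensity features are only extracted from tissue, not from
blood-pool cavities).

Note on units: heights are carried in centimetres throughout (values
around 160-180); the residualization step is affine-invariant so the
choice does not alter any downstream result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("female", "male")
CATEGORIES = ("shape", "first_order", "texture")
REGIONS = ("LV", "RV", "MYO")

#: Default category sizes of the radiomics manifest.
DEFAULT_MANIFEST_COUNTS = {"shape": 78, "first_order": 35, "texture": 141}

COHORT_COLUMNS = [
    "participant_id",
    "sex",
    "age",
    "height",
    "weight",
    "cvd_flag",
    "ethnicity_white",
]


class SchemaError(ValueError):
    """A table or manifest violates its declared schema."""


@dataclass
class CohortTable:
    """Validated per-participant demographics and confounds.

    Wraps a DataFrame with columns ``participant_id, sex, age, height,
    weight, cvd_flag, ethnicity_white``. Construction validates id
    uniqueness, sex codes, and positivity of age/height/weight.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"cohort table missing columns: {missing}")
        if df["participant_id"].duplicated().any():
            dupes = df.loc[df["participant_id"].duplicated(), "participant_id"]
            raise SchemaError(
                f"duplicate participant ids: {sorted(set(dupes))[:5]} ..."
            )
        bad_sex = set(df["sex"].unique()) - set(SEXES)
        if bad_sex:
            raise SchemaError(f"unknown sex codes: {sorted(bad_sex)}")
        if len(df):
            for col in ("age", "height", "weight"):
                vals = df[col].to_numpy(dtype=float)
                if not np.all(np.isfinite(vals)) or not np.all(vals > 0):
                    raise SchemaError(f"column {col!r} must be finite and > 0")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def ids(self) -> pd.Series:
        return self.data["participant_id"]

    @property
    def age(self) -> np.ndarray:
        return self.data["age"].to_numpy(dtype=float)

    def confounds(self, names: list[str]) -> pd.DataFrame:
        """Confound sub-table (e.g. ``["height", "weight"]``), row-aligned."""
        return self.data[list(names)].astype(float)


@dataclass
class FeatureManifest:
    """Radiomics feature catalogue: id, category, region per feature."""

    table: pd.DataFrame  # columns: feature_id, category, region

    def __post_init__(self) -> None:
        df = self.table
        for col in ("feature_id", "category", "region"):
            if col not in df.columns:
                raise SchemaError(f"manifest missing column {col!r}")
        if df["feature_id"].duplicated().any():
            dupes = df.loc[df["feature_id"].duplicated(), "feature_id"]
            raise SchemaError(f"duplicate feature ids: {sorted(set(dupes))[:5]}")
        bad_cat = set(df["category"]) - set(CATEGORIES)
        if bad_cat:
            raise SchemaError(f"unknown categories: {sorted(bad_cat)}")
        bad_reg = set(df["region"]) - set(REGIONS)
        if bad_reg:
            raise SchemaError(f"unknown regions: {sorted(bad_reg)}")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def feature_ids(self) -> list[str]:
        return self.table["feature_id"].tolist()

    def category_counts(self) -> dict[str, int]:
        return self.table["category"].value_counts().to_dict()

    def filter(self, category: str) -> "FeatureManifest":
        return FeatureManifest(self.table[self.table["category"] == category])


def default_manifest(counts: dict[str, int] | None = None) -> FeatureManifest:
    """Construct the default radiomics manifest.

    The defining property is the category/region structure: shape features
    cycle over LV, RV and MYO; first-order and texture features belong to
    the myocardium only. Feature ids are generated placeholders — the
    identities of the actual radiomics operators are opaque here, and a
    real extraction run supplies its own manifest via :func:`load_manifest`.
    """
    counts = dict(DEFAULT_MANIFEST_COUNTS if counts is None else counts)
    rows = []
    for i in range(counts.get("shape", 0)):
        region = REGIONS[i % 3]
        rows.append((f"shape_{region}_{i:03d}", "shape", region))
    for i in range(counts.get("first_order", 0)):
        rows.append((f"firstorder_MYO_{i:03d}", "first_order", "MYO"))
    for i in range(counts.get("texture", 0)):
        rows.append((f"texture_MYO_{i:03d}", "texture", "MYO"))
    return FeatureManifest(
        pd.DataFrame(rows, columns=["feature_id", "category", "region"])
    )


def load_manifest(path: str | Path | None = None) -> FeatureManifest:
    """Load a manifest from CSV (feature_id, category, region), or the default.

    Returns the validated manifest; category counts are logged.
    """
    if path is None:
        manifest = default_manifest()
    else:
        df = pd.read_csv(path)
        manifest = FeatureManifest(df)
    logger.info(
        "feature manifest: %d features (%s)",
        len(manifest),
        ", ".join(f"{k}={v}" for k, v in sorted(manifest.category_counts().items())),
    )
    return manifest


def apply_exclusions(raw: pd.DataFrame) -> CohortTable:
    """Filter a raw screening table to the analysis cohort.

    Retains rows with ``cvd_flag == False`` and ``ethnicity_white == True``;
    participants with prevalent cardiovascular disease are excluded because
    disease-driven remodelling would confound the aging signal, and the
    ethnic restriction matches the study population the normative model is
    built for. Counts removed per criterion are logged. Idempotent.
    """
    for col in ("cvd_flag", "ethnicity_white"):
        if col not in raw.columns:
            raise SchemaError(f"screening table missing flag column {col!r}")
    n0 = len(raw)
    cvd = raw["cvd_flag"].astype(bool)
    nonwhite = ~raw["ethnicity_white"].astype(bool)
    kept = raw.loc[~cvd & ~nonwhite].reset_index(drop=True)
    logger.info(
        "exclusions: %d screened, %d CVD-flagged, %d non-White, %d retained",
        n0,
        int(cvd.sum()),
        int((nonwhite & ~cvd).sum()),
        len(kept),
    )
    if len(kept) == 0:
        logger.warning("exclusion filter removed every participant")
    return CohortTable(kept[COHORT_COLUMNS])


def split_by_sex(cohort: CohortTable) -> dict[str, CohortTable]:
    """Partition a cohort into female and male strata.

    The strata are disjoint and exhaustive; an empty stratum is returned
    (and logged) rather than raised, so single-sex inputs simply skip the
    missing stratum downstream.
    """
    out: dict[str, CohortTable] = {}
    for sex in SEXES:
        sub = cohort.data[cohort.data["sex"] == sex]
        out[sex] = CohortTable(sub.reset_index(drop=True))
        if len(sub) == 0:
            logger.warning("sex stratum %r is empty; model fitting will be skipped", sex)
    return out


def validate_features(
    features: pd.DataFrame,
    cohort: CohortTable,
    manifest: FeatureManifest | None = None,
) -> pd.DataFrame:
    """Check row/column alignment of a feature matrix and drop degenerate columns.

    Rows must align with the cohort's participant ids (the index carries
    the ids). Columns of zero variance are uninformative for a linear age
    model and are dropped with a warning; all remaining values must be
    finite.
    """
    if len(features) != len(cohort):
        raise SchemaError(
            f"feature matrix has {len(features)} rows, cohort has {len(cohort)}"
        )
    if not np.array_equal(
        np.asarray(features.index), cohort.ids.to_numpy()
    ):
        raise SchemaError("feature matrix index does not match cohort participant ids")
    if manifest is not None:
        extra = set(features.columns) - set(manifest.feature_ids)
        missing = set(manifest.feature_ids) - set(features.columns)
        if extra or missing:
            raise SchemaError(
                f"feature columns disagree with manifest "
                f"(missing {sorted(missing)[:3]}, extra {sorted(extra)[:3]})"
            )
    vals = features.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise SchemaError("feature matrix contains non-finite values")
    sd = vals.std(axis=0)
    dead = features.columns[sd == 0.0]
    if len(dead):
        logger.warning("dropping %d zero-variance feature columns: %s",
                       len(dead), list(dead[:5]))
        features = features.drop(columns=dead)
    return features
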