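"""Pearson-correlation association engines.

Two scans share one machinery:

* **Feature profiling** — each radiomics feature, residualized for height,
  weight and age, is correlated with biological heart age; the family-wise
  Bonferroni factor is the number of features tested (254 by default).
* **Exposure-wide association scan (PheWAS)** — each exposure, residualized
  for age, height and weight, is correlated with the heart-age delta; the
  Bonferroni factor is the size of the exposure's category for that sex,
  so each of the 13 exposure families carries its own multiplicity burden.

Both report signed Pearson r, the raw two-sided p, the corrected
p = min(1, p_raw * m), and -log10 of the corrected p for plotting; a result
is significant when the corrected p < 0.05 (strict inequality). Ranking is
by ascending corrected p with ties broken by descending |r| ("most
informative first").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import SchemaError
from .deconfound import Residualizer

logger = logging.getLogger(__name__)

#: The 13 exposure categories. All but the last two apply to both sexes.
EXPOSURE_CATEGORIES = (
    "Abdominal MRI",
    "Blood biomarkers",
    "Cognitive function",
    "Education and employment",
    "Early life factors",
    "Health related outcomes",
    "Lifestyle and environment",
    "Mental health",
    "Physical measures",
    "Primary demographics",
    "Self-reported health conditions",
    "Female specific",
    "Male specific",
)

#: Default catalogue sizes: 666 shared + 30 female-specific + 5 male-specific
#: = 701 variables. The abdominal-MRI family has 16 variables, so its
#: Bonferroni multiplier is 16; the remaining 650 shared variables are spread
#: evenly over the other ten shared categories.
DEFAULT_CATALOGUE_COUNTS = {
    "Abdominal MRI": 16,
    "Blood biomarkers": 65,
    "Cognitive function": 65,
    "Education and employment": 65,
    "Early life factors": 65,
    "Health related outcomes": 65,
    "Lifestyle and environment": 65,
    "Mental health": 65,
    "Physical measures": 65,
    "Primary demographics": 65,
    "Self-reported health conditions": 65,
    "Female specific": 30,
    "Male specific": 5,
}

_CATEGORY_SLUGS = {
    "Abdominal MRI": "mri",
    "Blood biomarkers": "bio",
    "Cognitive function": "cf",
    "Education and employment": "ee",
    "Early life factors": "el",
    "Health related outcomes": "hr",
    "Lifestyle and environment": "le",
    "Mental health": "mh",
    "Physical measures": "pm",
    "Primary demographics": "pd",
    "Self-reported health conditions": "sr",
    "Female specific": "female_sp",
    "Male specific": "male_sp",
}


@dataclass
class ExposureCatalogue:
    """Exposure variable catalogue: id, category, sex applicability."""

    table: pd.DataFrame  # columns: variable_id, category, sex_applicability

    def __post_init__(self) -> None:
        df = self.table
        for col in ("variable_id", "category", "sex_applicability"):
            if col not in df.columns:
                raise SchemaError(f"catalogue missing column {col!r}")
        if df["variable_id"].duplicated().any():
            raise SchemaError("duplicate variable ids in exposure catalogue")
        bad = set(df["sex_applicability"]) - {"both", "female", "male"}
        if bad:
            raise SchemaError(f"unknown sex_applicability codes: {sorted(bad)}")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variable_ids(self) -> list[str]:
        return self.table["variable_id"].tolist()

    def for_sex(self, sex: str) -> pd.DataFrame:
        """Catalogue rows applicable to one sex (shared + sex-specific)."""
        mask = self.table["sex_applicability"].isin(["both", sex])
        return self.table[mask].reset_index(drop=True)

    def category_sizes(self, sex: str) -> dict[str, int]:
        """Per-category test counts for one sex — the Bonferroni factors."""
        return self.for_sex(sex)["category"].value_counts().to_dict()


def default_catalogue(
    counts: dict[str, int] | None = None,
) -> ExposureCatalogue:
    """Build the default 701-variable exposure catalogue.

    Variable ids are generated placeholders; real analyses supply their own
    catalogue CSV with the same three columns.
    """
    counts = dict(DEFAULT_CATALOGUE_COUNTS if counts is None else counts)
    rows = []
    for cat, n in counts.items():
        if cat not in _CATEGORY_SLUGS:
            raise SchemaError(f"unknown exposure category {cat!r}")
        applicability = (
            "female" if cat == "Female specific"
            else "male" if cat == "Male specific"
            else "both"
        )
        slug = _CATEGORY_SLUGS[cat]
        for i in range(n):
            rows.append((f"{slug}_{i:03d}", cat, applicability))
    return ExposureCatalogue(
        pd.DataFrame(rows, columns=["variable_id", "category", "sex_applicability"])
    )


def load_catalogue(path) -> ExposureCatalogue:
    """Load an exposure catalogue from CSV."""
    return ExposureCatalogue(pd.read_csv(path))


# p-values below the smallest positive normal double are floored there so
# that -log10 stays finite; capped corrected p-values render as -log10 = 0.
_P_FLOOR = np.finfo(float).tiny


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided p-value.

    The p-value comes from t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of
    freedom. Pairs with a missing value in either vector are dropped first.
    Returns ``(nan, nan)`` for constant vectors or n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(max(p, _P_FLOOR))


def bonferroni(p_raw: float, m: int) -> float:
    """Family-wise corrected p-value: min(1, p_raw * m)."""
    if m < 1:
        raise ValueError(f"family size must be >= 1, got {m}")
    return min(1.0, p_raw * m)


@dataclass
class AssociationResult:
    """Ranked association table for one scan (one family or one sex)."""

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


_RESULT_COLUMNS = [
    "variable_id",
    "category",
    "n_used",
    "r",
    "p_raw",
    "m",
    "p_corrected",
    "neg_log10_p",
    "significant",
    "rank",
]


def _assemble(rows: list[dict], alpha: float) -> pd.DataFrame:
    """Correct, flag, and rank a list of per-variable correlation rows.

    Non-evaluable rows (constant vectors, n below the minimum) keep NaN
    statistics, are never significant, and sort to the bottom.
    """
    df = pd.DataFrame(rows)
    corrected = np.minimum(1.0, df["p_raw"] * df["m"])
    df["p_corrected"] = corrected
    with np.errstate(divide="ignore"):
        df["neg_log10_p"] = -np.log10(corrected)
    df["significant"] = corrected < alpha
    df["significant"] = df["significant"].fillna(False).astype(bool)
    order = df.sort_values(
        by=["p_corrected", "r"],
        key=lambda s: s.abs() if s.name == "r" else s,
        ascending=[True, False],
        na_position="last",
        kind="mergesort",
    ).index
    df["rank"] = 0
    df.loc[order, "rank"] = np.arange(1, len(df) + 1)
    df = df.sort_values("rank").reset_index(drop=True)
    return df[[c for c in _RESULT_COLUMNS if c in df.columns]]


def profile_feature_age(
    features: pd.DataFrame,
    heart_age: np.ndarray,
    confounds: pd.DataFrame,
    manifest=None,
    alpha: float = 0.05,
) -> AssociationResult:
    """Correlate every radiomics feature with biological heart age.

    Features are residualized against the supplied confounds (height,
    weight and age in the reference analysis) before correlation, so the
    profile reflects heart-age-specific phenotype rather than body size or
    chronological age. One Bonferroni family: m = number of features tested.
    """
    if features.shape[1] == 0:
        raise ValueError("feature profiling needs at least one feature")
    res = Residualizer().fit(features, confounds)
    deconf = res.transform(features, confounds)
    m = deconf.shape[1]
    heart_age = np.asarray(heart_age, dtype=float)
    cat_map = (
        dict(zip(manifest.table["feature_id"], manifest.table["category"]))
        if manifest is not None
        else {}
    )
    rows = []
    for col in deconf.columns:
        r, p = pearson_with_p(deconf[col].to_numpy(), heart_age)
        rows.append(
            {
                "variable_id": col,
                "category": cat_map.get(col, ""),
                "n_used": int(np.isfinite(deconf[col]).sum()),
                "r": r,
                "p_raw": p,
                "m": m,
            }
        )
    return AssociationResult(_assemble(rows, alpha))


def phewas(
    delta: np.ndarray,
    exposures: pd.DataFrame,
    catalogue: ExposureCatalogue,
    confounds: pd.DataFrame,
    sex: str,
    alpha: float = 0.05,
    min_n: int = 100,
) -> AssociationResult:
    """Exposure-wide association scan of heart-age delta, per category.

    Each exposure applicable to ``sex`` is residualized against the
    confounds (age, height, weight), then correlated with the delta under
    pairwise complete-case handling. The Bonferroni factor for a variable
    is the size of its category for that sex. A positive r means higher
    exposure levels go with an older-than-actual heart.

    Variables with fewer than ``min_n`` complete pairs are reported as
    not-evaluable (NaN statistics) rather than silently dropped.
    """
    cat = catalogue.for_sex(sex)
    sizes = catalogue.category_sizes(sex)
    delta = np.asarray(delta, dtype=float)
    present = [v for v in cat["variable_id"] if v in exposures.columns]
    absent = set(cat["variable_id"]) - set(present)
    if absent:
        logger.warning("%d catalogue variables missing from exposure table", len(absent))
    cat = cat[cat["variable_id"].isin(present)]

    rows = []
    for _, entry in cat.iterrows():
        var = entry["variable_id"]
        x = exposures[var].to_numpy(dtype=float)
        ok = np.isfinite(x)
        n_used = int(ok.sum())
        m = sizes[entry["category"]]
        row = {
            "variable_id": var,
            "category": entry["category"],
            "n_used": n_used,
            "m": m,
            "r": float("nan"),
            "p_raw": float("nan"),
        }
        if n_used >= max(min_n, 3) and np.ptp(x[ok]) > 0:
            res = Residualizer().fit(
                pd.DataFrame({var: x[ok]}), confounds.iloc[ok]
            )
            if res.kept_columns:  # exposure not fully explained by confounds
                deconf = res.transform(
                    pd.DataFrame({var: x[ok]}), confounds.iloc[ok]
                )
                r, p = pearson_with_p(deconf[var].to_numpy(), delta[ok])
                row["r"], row["p_raw"] = r, p
        else:
            logger.warning("exposure %s not evaluable (n_used=%d)", var, n_used)
        rows.append(row)
    if not rows:
        raise ValueError(f"no exposures applicable to sex={sex!r}")
    return AssociationResult(_assemble(rows, alpha))
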