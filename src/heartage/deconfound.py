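"""Confound residualization with a strict fit/apply split.

Each target column is replaced by its residual from an ordinary
least-squares fit on the confounds (plus intercept); residuals are then
standardized to zero mean and unit variance using moments stored at fit
time. Applying a fitted residualizer to new data reuses the stored
coefficients and moments, so cross-validation folds can be deconfounded
without touching held-out rows (``mode=strict`` in the pipeline).

The feature model uses height and weight as confounds; the association
stages additionally include age. Confound sets are always passed in
explicitly.

In-sample, residuals are exactly orthogonal to every confound column, and
the whole operation is invariant to affine rescaling of the confounds
(height in metres or centimetres gives identical output).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_ZERO_VAR_TOL = 1e-12


class RankDeficientConfounds(ValueError):
    """The confound design matrix is not full rank."""


def _design(C: pd.DataFrame) -> np.ndarray:
    """Intercept + confound columns as a dense design matrix."""
    Cm = np.asarray(C, dtype=float)
    return np.column_stack([np.ones(len(Cm)), Cm])


class Residualizer:
    """Per-column OLS residualization followed by standardization.

    Attributes (after ``fit``):

    confound_names : ordered confound column names
    coef_ : (n_confounds + 1, n_kept) array, intercept row first
    mean_, sd_ : residual moments per kept column (mean is ~0 in-sample
        by construction but stored for the out-of-sample apply path)
    kept_columns / dropped_columns : columns retained / dropped because
        their residual variance was (numerically) zero
    """

    def __init__(self) -> None:
        self.confound_names: list[str] | None = None
        self.kept_columns: list[str] = []
        self.dropped_columns: list[str] = []
        self.coef_: np.ndarray | None = None
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, X: pd.DataFrame, C: pd.DataFrame) -> "Residualizer":
        if len(X) != len(C):
            raise ValueError(f"row mismatch: X has {len(X)}, confounds {len(C)}")
        Cvals = np.asarray(C, dtype=float)
        if not np.all(np.isfinite(Cvals)):
            raise ValueError("confound table contains missing/non-finite values")
        D = _design(C)
        rank = np.linalg.matrix_rank(D)
        if rank < D.shape[1]:
            # identify offending columns by incremental rank
            collinear = []
            cols = [np.ones(len(D))]
            for name in C.columns:
                cand = np.column_stack(cols + [np.asarray(C[name], dtype=float)])
                if np.linalg.matrix_rank(cand) == len(cols):
                    collinear.append(name)
                else:
                    cols.append(np.asarray(C[name], dtype=float))
            raise RankDeficientConfounds(
                f"confound design is rank deficient; collinear columns: {collinear}"
            )
        Xv = np.asarray(X, dtype=float)
        beta, *_ = np.linalg.lstsq(D, Xv, rcond=None)
        resid = Xv - D @ beta
        mean = resid.mean(axis=0)
        sd = resid.std(axis=0, ddof=0)
        scale = np.abs(Xv).max(axis=0) + 1.0
        keep = sd > _ZERO_VAR_TOL * scale

        self.confound_names = list(C.columns)
        self.kept_columns = [c for c, k in zip(X.columns, keep) if k]
        self.dropped_columns = [c for c, k in zip(X.columns, keep) if not k]
        if self.dropped_columns:
            logger.warning(
                "residualizer dropped %d zero-residual-variance columns: %s",
                len(self.dropped_columns),
                self.dropped_columns[:5],
            )
        self.coef_ = beta[:, keep]
        self.mean_ = mean[keep]
        self.sd_ = sd[keep]
        return self

    def transform(self, X: pd.DataFrame, C: pd.DataFrame) -> pd.DataFrame:
        """Residualize and standardize using the stored fit."""
        if self.coef_ is None:
            raise RuntimeError("Residualizer not fitted")
        if list(C.columns) != self.confound_names:
            raise ValueError(
                f"confound columns {list(C.columns)} != fitted {self.confound_names}"
            )
        missing = [c for c in self.kept_columns if c not in X.columns]
        if missing:
            raise ValueError(f"input lacks fitted columns: {missing[:5]}")
        Xv = np.asarray(X[self.kept_columns], dtype=float)
        D = _design(C)
        resid = Xv - D @ self.coef_
        out = (resid - self.mean_) / self.sd_
        return pd.DataFrame(out, columns=self.kept_columns, index=X.index)

    def fit_transform(self, X: pd.DataFrame, C: pd.DataFrame) -> pd.DataFrame:
        return self.fit(X, C).transform(X, C)

    # -- serialization --------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "confound_names": self.confound_names,
            "kept_columns": self.kept_columns,
            "dropped_columns": self.dropped_columns,
            "coef": self.coef_.tolist(),
            "mean": self.mean_.tolist(),
            "sd": self.sd_.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "Residualizer":
        payload = json.loads(Path(path).read_text())
        model = cls()
        model.confound_names = payload["confound_names"]
        model.kept_columns = payload["kept_columns"]
        model.dropped_columns = payload["dropped_columns"]
        model.coef_ = np.asarray(payload["coef"], dtype=float)
        model.mean_ = np.asarray(payload["mean"], dtype=float)
        model.sd_ = np.asarray(payload["sd"], dtype=float)
        return model
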