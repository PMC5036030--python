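"""Formula handling, covariate standardization, design matrices and link functions.

Occupancy and detection probabilities are modelled on the logit scale as
linear functions of standardized site covariates, optionally including
two-way interaction (product) terms.  This module owns the small formula
grammar shared by the whole package: terms joined by ``+``, two-way
interactions written ``a * b`` (which expands, conventionally, to the main
effects ``a`` and ``b`` plus their product), ``1`` for an intercept-only
model.  Column order in every design matrix is fixed — intercept first, then
main effects in declaration order, then interaction products — so that
parameter vectors are reproducible across runs.

Standardization (mean 0, sample standard deviation 1, denominator ``n − 1``)
is fitted on the training covariate table and the centering/scaling record is
reused verbatim for prediction grids; interaction columns are products of the
*standardized* main-effect columns and are not themselves re-standardized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit as _logit
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ModelFormula",
    "DesignMatrix",
    "FormulaError",
    "DegenerateCovariateError",
    "Standardizer",
    "standardize",
    "build_design_matrix",
    "logit",
    "inv_logit",
]

INTERCEPT = "(Intercept)"


class FormulaError(ValueError):
    """A formula references an unknown covariate or is malformed."""


class DegenerateCovariateError(ValueError):
    """A covariate column has zero variance and cannot be standardized."""


@dataclass(frozen=True)
class ModelFormula:
    """A parsed linear-predictor formula.

    Attributes
    ----------
    main_terms : tuple of str
        Covariate names entering as main effects, in declaration order.
        Interactions contribute their members here (conventional expansion).
    interaction_terms : tuple of (str, str)
        Two-way interaction pairs, in declaration order.  Each pair is stored
        in the order first written; the product is symmetric.
    """

    main_terms: tuple[str, ...] = ()
    interaction_terms: tuple[tuple[str, str], ...] = ()

    @classmethod
    def parse(cls, formula: str) -> "ModelFormula":
        """Parse a formula string such as ``"pop * elev + for"`` or ``"1"``."""
        mains: list[str] = []
        inters: list[tuple[str, str]] = []
        text = (formula or "").strip()
        if text in ("", "1", "~1", "."):
            return cls()
        for raw in text.split("+"):
            term = raw.strip()
            if not term:
                raise FormulaError(f"empty term in formula {formula!r}")
            if "*" in term:
                parts = [p.strip() for p in term.split("*")]
                if len(parts) != 2 or not all(parts):
                    raise FormulaError(
                        f"only two-way interactions are supported: {term!r}"
                    )
                a, b = parts
                if a == b:
                    raise FormulaError(f"self-interaction {term!r} is not allowed")
                pair = (a, b)
                if pair in inters or (b, a) in inters:
                    raise FormulaError(f"duplicate interaction term {term!r}")
                inters.append(pair)
                for name in (a, b):
                    if name not in mains:
                        mains.append(name)
            else:
                if term == "1":
                    continue
                if term in mains:
                    raise FormulaError(f"duplicate main effect {term!r}")
                mains.append(term)
        return cls(tuple(mains), tuple(inters))

    @property
    def covariates(self) -> tuple[str, ...]:
        return self.main_terms

    @property
    def column_labels(self) -> tuple[str, ...]:
        labels = [INTERCEPT, *self.main_terms]
        labels += [f"{a}:{b}" for a, b in self.interaction_terms]
        return tuple(labels)

    @property
    def n_columns(self) -> int:
        return 1 + len(self.main_terms) + len(self.interaction_terms)

    def __str__(self) -> str:
        if not self.main_terms:
            return "1"
        # emit each interaction at the position of its first member so that
        # re-parsing preserves term order; absorbed mains are implied
        parts: list[str] = []
        emitted: set[tuple[str, str]] = set()
        for name in self.main_terms:
            pair = next(
                (p for p in self.interaction_terms if name in p and p not in emitted),
                None,
            )
            if pair is not None:
                parts.append(f"{pair[0]} * {pair[1]}")
                emitted.add(pair)
            elif not any(name in p for p in self.interaction_terms):
                parts.append(name)
        return " + ".join(parts) if parts else "1"


@dataclass
class DesignMatrix:
    """A dense design matrix with labelled columns and row identifiers."""

    values: np.ndarray
    column_labels: tuple[str, ...]
    row_ids: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("design matrix must be 2-dimensional")
        if self.values.shape[1] != len(self.column_labels):
            raise ValueError("column label count does not match matrix width")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


class Standardizer(BaseEstimator, TransformerMixin):
    """Center and scale covariate columns to mean 0, sample sd 1 (ddof=1).

    The fitted record (``mean_``, ``scale_``) is applied unchanged to new
    tables (e.g. a prediction grid) so that training and prediction share one
    covariate scale.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "Standardizer":
        X = _as_numeric_frame(X)
        mean = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1)
        bad = [c for c in X.columns if not np.isfinite(scale[c]) or scale[c] == 0.0]
        if bad:
            raise DegenerateCovariateError(
                f"zero-variance covariate column(s): {', '.join(map(str, bad))}"
            )
        self.columns_ = tuple(X.columns)
        self.mean_ = mean
        self.scale_ = scale
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check_fitted()
        X = _as_numeric_frame(X)
        missing = [c for c in self.columns_ if c not in X.columns]
        if missing:
            raise KeyError(f"missing covariate column(s): {', '.join(missing)}")
        out = X.copy()
        for c in self.columns_:
            out[c] = (X[c] - self.mean_[c]) / self.scale_[c]
        return out

    def inverse_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check_fitted()
        out = X.copy()
        for c in self.columns_:
            if c in out.columns:
                out[c] = out[c] * self.scale_[c] + self.mean_[c]
        return out

    def _check_fitted(self) -> None:
        if not hasattr(self, "mean_"):
            raise RuntimeError("Standardizer is not fitted")


def _as_numeric_frame(X: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(X)
    for c in X.columns:
        if not np.issubdtype(np.asarray(X[c]).dtype, np.number):
            raise TypeError(f"covariate column {c!r} is not numeric")
    if X.isna().any().any():
        raise ValueError("covariate table contains missing values")
    return X


def standardize(covariates: pd.DataFrame) -> tuple[pd.DataFrame, Standardizer]:
    """Standardize every column; return the table and the fitted record."""
    record = Standardizer().fit(covariates)
    return record.transform(covariates), record


def build_design_matrix(
    formula: ModelFormula | str, covariates: pd.DataFrame
) -> DesignMatrix:
    """Build the design matrix for *formula* from standardized covariates.

    Columns are ordered intercept, main effects, interaction products; each
    interaction column is the elementwise product of its two (standardized)
    main-effect columns.
    """
    if isinstance(formula, str):
        formula = ModelFormula.parse(formula)
    covariates = pd.DataFrame(covariates)
    unknown = [c for c in formula.covariates if c not in covariates.columns]
    if unknown:
        raise FormulaError(f"unknown covariate(s): {', '.join(unknown)}")
    n = len(covariates)
    cols = [np.ones(n)]
    for name in formula.main_terms:
        cols.append(np.asarray(covariates[name], dtype=float))
    for a, b in formula.interaction_terms:
        cols.append(
            np.asarray(covariates[a], dtype=float)
            * np.asarray(covariates[b], dtype=float)
        )
    values = np.column_stack(cols) if cols else np.ones((n, 1))
    row_ids = tuple(covariates.index)
    return DesignMatrix(values, formula.column_labels, row_ids)


def logit(x):
    """Log-odds of a probability in the open interval (0, 1)."""
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise ValueError("logit is defined on the open interval (0, 1)")
    out = _logit(x)
    return float(out) if out.ndim == 0 else out


def inv_logit(x):
    """Numerically stable inverse logit (expit)."""
    out = expit(np.asarray(x, dtype=float))
    return float(out) if out.ndim == 0 else out
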