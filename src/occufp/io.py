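"""Readers, writers and run configuration.

CSV dialect (fixed once): comma-separated, UTF-8, ``.`` decimal, empty
string for missing.  Detections: header ``site_id,rep_1,…,rep_J``, entries
0/1 or empty.  Covariates: ``site_id,<name>…``, numeric, no missing values.
Prediction grid: ``cell_id[,easting,northing],<covariates>…``; unused extra
columns pass through to the export.  Tables align to the detection matrix by
``site_id`` (never by row order).

The run configuration is a YAML mapping validated on load; see
:class:`RunConfig` for the schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParseError",
    "AlignmentError",
    "read_detections",
    "read_covariates",
    "read_grid",
    "align_covariates",
    "RunConfig",
]


class ParseError(ValueError):
    """A CSV value violates the documented dialect."""


class AlignmentError(KeyError):
    """Keys in one table do not match the other's."""


def read_detections(path: str | Path) -> pd.DataFrame:
    """Read a ``site_id,rep_1..rep_J`` detection-history CSV.

    Entries must be 0, 1 or empty (missing).  Duplicate site ids and any
    other value are errors naming the offending row/column.
    """
    df = pd.read_csv(path)
    if "site_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'site_id'")
    if df["site_id"].duplicated().any():
        dupes = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise ParseError(f"{path}: duplicate site_id value(s): {dupes}")
    df = df.set_index("site_id")
    rep_cols = [c for c in df.columns if c.startswith("rep_")]
    if not rep_cols:
        raise ParseError(f"{path}: no replicate columns (rep_1, rep_2, ...)")
    df = df[rep_cols]
    for col in rep_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        raw_na = df[col].isna()
        bad = vals.notna() & ~vals.isin([0, 1])
        unparsed = vals.isna() & ~raw_na
        if bad.any() or unparsed.any():
            site = df.index[(bad | unparsed)][0]
            raise ParseError(
                f"{path}: non-binary entry at site_id={site}, column {col}"
            )
        df[col] = vals.astype(float)
    return df


def _read_keyed_table(path: str | Path, key: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    if key not in df.columns:
        raise ParseError(f"{path}: missing required column {key!r}")
    if df[key].duplicated().any():
        raise ParseError(f"{path}: duplicate {key} values")
    return df.set_index(key)


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read a ``site_id``-keyed covariate table; numeric, no missing cells."""
    df = _read_keyed_table(path, "site_id")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            site = df.index[vals.isna()][0]
            raise ParseError(
                f"{path}: missing or non-numeric covariate at "
                f"site_id={site}, column {col} (no imputation is performed)"
            )
        df[col] = vals.astype(float)
    return df


def read_grid(path: str | Path) -> pd.DataFrame:
    """Read a ``cell_id``-keyed prediction grid; extra columns pass through."""
    return _read_keyed_table(path, "cell_id")


def align_covariates(covariates: pd.DataFrame, detections: pd.DataFrame) -> pd.DataFrame:
    """Reorder covariate rows to the detection matrix's site ids."""
    missing = [s for s in detections.index if s not in covariates.index]
    if missing:
        raise AlignmentError(
            f"covariate table lacks site_id value(s): {missing[:10]}"
        )
    return covariates.loc[detections.index]


@dataclass
class RunConfig:
    """Validated run configuration.

    YAML schema (all sections optional unless a step requires them)::

        paths:
          detections: detections.csv
          covariates: covariates.csv
          grid: grid.csv            # optional
          out_dir: results/
        candidates:
          covariates: [elev, rug, for, pop]   # enumerate over these, or
          specs:                               # explicit list
            - {psi: "pop + rug", p: "elev"}
        selection:
          delta_aic: 2.0
          phase2_cut: 2.0
        optimizer:
          restarts: 5
          tol: 1.0e-8
          seed: 0
        simulate:                  # when used as a generator
          n_sites: 225
          n_replicates: 6
          covariates: [elev, rug, for, pop]
          beta_psi: {"(Intercept)": 0.0, pop: -0.9}
          alpha_p: {"(Intercept)": 0.4}
          p10: 0.03
          missing_rate: 0.0
    """

    paths: dict = field(default_factory=dict)
    candidates: dict = field(default_factory=dict)
    delta_aic: float = 2.0
    phase2_cut: float = 2.0
    restarts: int = 5
    tol: float = 1e-8
    seed: int = 0
    simulate: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ParseError(f"{path}: run config must be a mapping")
        sel = raw.get("selection", {}) or {}
        opt = raw.get("optimizer", {}) or {}
        cfg = cls(
            paths=raw.get("paths", {}) or {},
            candidates=raw.get("candidates", {}) or {},
            delta_aic=float(sel.get("delta_aic", 2.0)),
            phase2_cut=float(sel.get("phase2_cut", 2.0)),
            restarts=int(opt.get("restarts", 5)),
            tol=float(opt.get("tol", 1e-8)),
            seed=int(opt.get("seed", 0)),
            simulate=raw.get("simulate"),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.delta_aic <= 0 or self.phase2_cut <= 0:
            raise ValueError("selection thresholds must be > 0")
        if self.restarts < 1:
            raise ValueError("optimizer restarts must be >= 1")
        if self.tol <= 0:
            raise ValueError("optimizer tol must be > 0")
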