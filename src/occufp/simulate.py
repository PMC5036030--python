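"""Simulation of detection/non-detection datasets with known truth.

The generator mirrors the interview-survey design the fitting code targets:
``M = 225`` sites (5 x 5 km hunting grounds), ``J = 6`` spatial replicates
(hunting zones) per site, four standardized site covariates (mean elevation,
terrain ruggedness, forest area, density of human settlements), occupancy and
detection logit-linear in those covariates, and a constant false-positive
probability ``p10`` applied at unoccupied sites.  Covariates are drawn
standard normal by default because the analysis always operates on
standardized covariates; a uniform generator is available for raw-scale
experiments and is standardized downstream by the fitting code.

Truth (latent state ``z``, per-site ``psi``, per-replicate ``p``) is kept in
a separate sidecar table so fitting code never sees it.  One explicit RNG
stream per dataset makes every dataset bit-reproducible from its config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import INTERCEPT, ModelFormula, build_design_matrix

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "STUDY_COVARIATES",
    "generate_covariates",
    "simulate_occupancy",
    "simulate_detections",
    "simulate_dataset",
    "write_dataset",
]

#: The four site covariates of the reference survey design.
STUDY_COVARIATES: tuple[str, ...] = ("elev", "rug", "for", "pop")

_GENERATORS = {"standard_normal", "uniform"}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated survey.

    ``beta_psi`` and ``alpha_p`` map term names — ``"(Intercept)"``, a
    declared covariate, or a product ``"a:b"`` of two declared covariates —
    to coefficients on the logit scale.
    """

    n_sites: int = 225
    n_replicates: int = 6
    covariate_spec: tuple[tuple[str, str], ...] = tuple(
        (name, "standard_normal") for name in STUDY_COVARIATES
    )
    beta_psi: dict = field(default_factory=lambda: {INTERCEPT: 0.0})
    alpha_p: dict = field(default_factory=lambda: {INTERCEPT: 0.0})
    p10: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_replicates < 1:
            raise ValueError("n_sites and n_replicates must be >= 1")
        if not 0.0 <= self.p10 < 1.0:
            raise ValueError("p10 must lie in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        object.__setattr__(self, "covariate_spec", tuple(map(tuple, self.covariate_spec)))
        names = [n for n, _ in self.covariate_spec]
        if len(set(names)) != len(names):
            raise ValueError("duplicate covariate names in covariate_spec")
        for coef_map in (self.beta_psi, self.alpha_p):
            for term in coef_map:
                self._check_term(term, names)

    @staticmethod
    def _check_term(term: str, names: list[str]) -> None:
        if term == INTERCEPT or term in names:
            return
        if ":" in term:
            a, _, b = term.partition(":")
            if a in names and b in names and a != b:
                return
        raise ValueError(f"coefficient term {term!r} is not resolvable")

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.covariate_spec)


@dataclass
class SimulatedDataset:
    """A simulated survey with its generating truth attached."""

    detections: pd.DataFrame  # site_id index, rep_1..rep_J columns; NaN = missing
    site_covariates: pd.DataFrame  # site_id index
    true_z: np.ndarray
    true_psi: np.ndarray
    true_p: np.ndarray  # (M, J)
    config: SimulationConfig

    def detection_matrix(self) -> np.ndarray:
        return self.detections.to_numpy(dtype=float)


def generate_covariates(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw the site covariate table described by ``config.covariate_spec``."""
    if not config.covariate_spec:
        raise ValueError("covariate_spec must be non-empty")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    cols = {}
    for name, generator in config.covariate_spec:
        if generator == "standard_normal":
            cols[name] = rng.standard_normal(config.n_sites)
        elif generator == "uniform":
            cols[name] = rng.uniform(0.0, 1.0, config.n_sites)
        else:
            raise ValueError(
                f"unknown covariate generator {generator!r}; "
                f"expected one of {sorted(_GENERATORS)}"
            )
    index = pd.Index(range(1, config.n_sites + 1), name="site_id")
    return pd.DataFrame(cols, index=index)


def _linear_predictor(coef_map: dict, covariates: pd.DataFrame) -> np.ndarray:
    eta = np.zeros(len(covariates))
    for term, coef in coef_map.items():
        if term == INTERCEPT:
            eta += coef
        elif ":" in term:
            a, _, b = term.partition(":")
            eta += coef * covariates[a].to_numpy() * covariates[b].to_numpy()
        else:
            eta += coef * covariates[term].to_numpy()
    return eta


def simulate_occupancy(
    config: SimulationConfig,
    covariates: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw latent occupancy states: ``z_i ~ Bernoulli(inv_logit(x_i' beta))``."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    true_psi = expit(_linear_predictor(config.beta_psi, covariates))
    true_z = rng.binomial(1, true_psi)
    return true_z, true_psi


def simulate_detections(
    config: SimulationConfig,
    covariates: pd.DataFrame,
    true_z: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the detection matrix; returns ``(Y, true_p)``.

    Occupied sites detect with ``p_ij = inv_logit(detection predictor)``;
    unoccupied sites "detect" (false positives) with constant ``p10``.
    """
    true_z = np.asarray(true_z)
    if len(true_z) != config.n_sites:
        raise ValueError("true_z length must equal n_sites")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    M, J = config.n_sites, config.n_replicates
    true_p = np.broadcast_to(
        expit(_linear_predictor(config.alpha_p, covariates))[:, None], (M, J)
    ).copy()
    rate = np.where(true_z[:, None] == 1, true_p, config.p10)
    y = rng.binomial(1, rate).astype(float)
    if config.missing_rate > 0.0:
        miss = rng.uniform(size=(M, J)) < config.missing_rate
        # keep >=1 observed replicate per site so the likelihood is defined
        all_missing = miss.all(axis=1)
        if np.any(all_missing):
            keep = rng.integers(0, J, size=int(all_missing.sum()))
            miss[np.flatnonzero(all_missing), keep] = False
        y[miss] = np.nan
    return y, true_p


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator under a single seeded RNG stream."""
    rng = np.random.default_rng(config.seed)
    covariates = generate_covariates(config, rng)
    true_z, true_psi = simulate_occupancy(config, covariates, rng)
    y, true_p = simulate_detections(config, covariates, true_z, rng)
    rep_cols = [f"rep_{j}" for j in range(1, config.n_replicates + 1)]
    detections = pd.DataFrame(y, index=covariates.index, columns=rep_cols)
    return SimulatedDataset(detections, covariates, true_z, true_psi, true_p, config)


def write_dataset(
    dataset: SimulatedDataset,
    detections_path: str | Path,
    covariates_path: str | Path,
    truth_path: str | Path | None = None,
) -> None:
    """Write detections and covariates as CSV; truth goes to a sidecar only.

    Missing detections serialize as empty cells.  The truth sidecar
    (``site_id,z,psi,p_1..p_J,seed``) is never among the inputs a fit
    consumes.
    """
    det = dataset.detections.copy()
    det.to_csv(detections_path, float_format="%.0f", na_rep="")
    dataset.site_covariates.to_csv(covariates_path)
    if truth_path is not None:
        J = dataset.config.n_replicates
        truth = pd.DataFrame(
            {"z": dataset.true_z, "psi": dataset.true_psi},
            index=dataset.site_covariates.index,
        )
        for j in range(J):
            truth[f"p_{j + 1}"] = dataset.true_p[:, j]
        truth["seed"] = dataset.config.seed
        truth.to_csv(truth_path)
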