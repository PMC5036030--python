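"""Candidate sets, AIC ranking, the two-phase workflow and model averaging.

Model selection proceeds in two phases.  Phase 1 fits every candidate as a
conventional occupancy model (false negatives only) and ranks by AIC.
Phase 2 refits each phase-1 model within ΔAIC < 2 of the best as its
misclassification counterpart — identical ψ and p formulas plus one scalar
false-positive probability ``p10`` — and the final ranking covers the union
of those top conventional models and their counterparts, with Akaike weights
``w_m ∝ exp(−ΔAIC_m / 2)`` renormalized to sum to 1 over that union.

Model-averaged predictions use the models within ΔAIC < 2 of the final best,
their weights renormalized, averaging on the probability scale.  For
misclassification models the averaged detection probability is ``p11``
(detection given presence); ``p10`` is reported separately.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .fitting import ModelSpec, OccupancyModel, fit_spec

__all__ = [
    "CandidateSet",
    "SelectionError",
    "enumerate_candidates",
    "rank_models",
    "two_phase_select",
    "model_average",
]

DEFAULT_DELTA_AIC = 2.0


class SelectionError(RuntimeError):
    """No usable (converged) model fits to select among."""


@dataclass(frozen=True)
class CandidateSet:
    """An ordered set of candidate specs with its provenance."""

    specs: tuple[ModelSpec, ...]
    provenance: str = "user-listed"

    def __post_init__(self) -> None:
        labels = [s.label for s in self.specs]
        if len(set(labels)) != len(labels):
            raise ValueError("candidate labels must be unique")

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)


def _component_formulas(
    covariates: tuple[str, ...], allow_interactions: bool
) -> list[str]:
    """All main-effect subsets, each optionally with one two-way interaction."""
    out: list[str] = []
    names = list(covariates)
    for r in range(len(names) + 1):
        for subset in combinations(names, r):
            out.append(" + ".join(subset) if subset else "1")
            if allow_interactions:
                for a, b in combinations(subset, 2):
                    rest = [c for c in subset if c not in (a, b)]
                    out.append(" + ".join([f"{a} * {b}", *rest]))
    return out


def enumerate_candidates(
    covariate_names,
    allow_interactions: bool = True,
    max_candidates: int = 2000,
) -> CandidateSet:
    """Enumerate conventional candidates: ψ-subsets crossed with p-subsets.

    Each component ranges over every subset of main effects, optionally
    augmented by a single two-way interaction between covariates present in
    that component.  Counts above ``max_candidates`` are refused (pass an
    explicit spec list instead).
    """
    names = tuple(covariate_names)
    if not 1 <= len(names) <= 8:
        raise ValueError("enumeration supports 1-8 covariates")
    comp = _component_formulas(names, allow_interactions)
    total = len(comp) ** 2
    if total > max_candidates:
        raise ValueError(
            f"enumeration would produce {total} candidates "
            f"(> max_candidates={max_candidates}); supply an explicit list"
        )
    specs = tuple(
        ModelSpec(psi_f, p_f, misclassification=False)
        for psi_f in comp
        for p_f in comp
    )
    return CandidateSet(specs, provenance="enumerated")


def rank_models(fits) -> pd.DataFrame:
    """Rank fitted models by AIC with ΔAIC and Akaike weights.

    Non-converged fits are excluded (with a logged reason in the returned
    frame's ``attrs['excluded']``).  Ties break by label for stability.
    """
    fits = list(fits)
    excluded = [f.spec_.label for f in fits if not f.converged_]
    usable = [f for f in fits if f.converged_]
    if not usable:
        raise SelectionError("no converged model fits to rank")
    rows = [
        {
            "label": f.spec_.label,
            "class": f.spec_.model_class,
            "k": f.n_params_,
            "logLik": f.loglik_,
            "AIC": f.aic_,
        }
        for f in usable
    ]
    table = pd.DataFrame(rows).sort_values(["AIC", "label"], kind="stable")
    table["dAIC"] = table["AIC"] - table["AIC"].min()
    rel = np.exp(-0.5 * table["dAIC"].to_numpy())
    table["weight"] = rel / rel.sum()
    table = table.reset_index(drop=True)
    table.attrs["excluded"] = excluded
    return table


def _spec_seed(label: str, random_state: int) -> int:
    # stable across runs/processes (unlike hash()); keeps seeds below 2^31
    return (int(random_state) + zlib.crc32(label.encode())) % (2**31 - 1)


def two_phase_select(
    candidates: CandidateSet,
    covariates: pd.DataFrame,
    detections: np.ndarray,
    phase2_cut: float = DEFAULT_DELTA_AIC,
    random_state: int = 0,
    **fit_options,
) -> tuple[pd.DataFrame, dict[str, OccupancyModel]]:
    """Run the conventional→misclassification two-phase selection.

    Returns the final ranking table over the union of phase-1 top models and
    their misclassification counterparts, plus every fitted model by label.
    Per-model fitting errors are recorded, not raised, so one pathological
    candidate cannot abort the run.
    """
    if any(s.misclassification for s in candidates):
        raise ValueError("phase-1 candidates must be conventional models")

    failures: dict[str, str] = {}
    fits: dict[str, OccupancyModel] = {}

    def _fit(spec: ModelSpec) -> OccupancyModel | None:
        try:
            model = fit_spec(
                spec,
                covariates,
                detections,
                random_state=_spec_seed(spec.label, random_state),
                **fit_options,
            )
        except Exception as exc:  # per-model isolation
            failures[spec.label] = f"{type(exc).__name__}: {exc}"
            return None
        fits[spec.label] = model
        return model

    phase1 = [m for spec in candidates if (m := _fit(spec)) is not None]
    phase1_rank = rank_models(phase1)
    top = phase1_rank[phase1_rank["dAIC"] < phase2_cut]

    final_models: list[OccupancyModel] = []
    for label in top["label"]:
        om = fits[label]
        final_models.append(om)
        mm_spec = ModelSpec(om.psi_formula, om.p_formula, misclassification=True)
        mm = _fit(mm_spec)
        if mm is not None:
            final_models.append(mm)

    ranking = rank_models(final_models)
    ranking.attrs["phase1"] = phase1_rank
    ranking.attrs["failures"] = failures
    return ranking, fits


def model_average(
    fits: dict[str, OccupancyModel],
    ranking: pd.DataFrame,
    X: pd.DataFrame,
    delta_cut: float = DEFAULT_DELTA_AIC,
) -> pd.DataFrame:
    """ΔAIC-thresholded model-averaged ψ and p for each row of ``X``.

    Restricts to models with ΔAIC < ``delta_cut``, renormalizes their Akaike
    weights, and averages predicted probabilities on the probability scale.
    Returns columns ``psi_avg``, ``p_avg`` and ``p10_avg`` (the
    weight-averaged p10, 0 for conventional models; NaN-free).
    """
    top = ranking[ranking["dAIC"] < delta_cut]
    if top.empty:
        raise SelectionError("no models within the ΔAIC threshold")
    w = top["weight"].to_numpy()
    w = w / w.sum()
    psi = np.zeros(len(X))
    p = np.zeros(len(X))
    p10 = 0.0
    for weight, label in zip(w, top["label"]):
        model = fits[label]
        psi += weight * model.predict_psi(X)
        p += weight * model.predict_p(X)
        p10 += weight * (model.p10_ or 0.0)
    out = pd.DataFrame({"psi_avg": psi, "p_avg": p}, index=pd.DataFrame(X).index)
    out.attrs["p10_avg"] = float(p10)
    out.attrs["weights"] = dict(zip(top["label"], w))
    return out
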