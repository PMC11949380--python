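"""Education-standardized (counterfactual) transition probabilities.

Trends in the unadjusted metrics partly reflect the changing educational
composition of the population. To separate that compositional change from
within-group change, period-specific transition probabilities are recomputed
under a fixed education distribution: the person-period share of each
education level pooled over the whole observation window. Mixing happens on
the transition probabilities themselves (entrywise convex combination of the
education-specific matrices), so the standardized matrices remain
row-stochastic by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import PersonPeriodTable
from .estimation import TransitionProbs, aggregate_transitions
from .states import EDUCATION_LEVELS

__all__ = ["EducationWeights", "pooled_education_weights", "standardize_transition_probs"]


@dataclass(frozen=True)
class EducationWeights:
    """Fixed education distribution used for direct standardization."""

    weights: dict[str, float]
    provenance: str = "pooled"

    def __post_init__(self) -> None:
        if set(self.weights) != set(EDUCATION_LEVELS):
            raise ValueError(f"weights must cover {EDUCATION_LEVELS}")
        vals = np.array([self.weights[e] for e in EDUCATION_LEVELS])
        if np.any(vals < 0):
            raise ValueError("weights must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")

    def __getitem__(self, level: str) -> float:
        return self.weights[level]

    def to_dict(self) -> dict:
        return {"weights": dict(self.weights), "provenance": self.provenance}


def pooled_education_weights(
    data: PersonPeriodTable | pd.DataFrame, gender: str | None = None
) -> EducationWeights:
    """Person-period share of each education level pooled over all periods.

    Optionally restricted to one gender (standardization is done within
    gender contexts). Raises on empty data.
    """
    cells = aggregate_transitions(data)
    if gender is not None:
        cells = cells[cells["gender"] == gender]
    if cells.empty or cells["count"].sum() == 0:
        raise ValueError("no observations to pool education shares from")
    totals = cells.groupby("education", observed=True)["count"].sum()
    grand = float(totals.sum())
    weights = {e: float(totals.get(e, 0)) / grand for e in EDUCATION_LEVELS}
    tag = "pooled" if gender is None else f"pooled/{gender}"
    return EducationWeights(weights=weights, provenance=tag)


def standardize_transition_probs(
    probs_by_education: dict[str, TransitionProbs], weights: EducationWeights
) -> TransitionProbs:
    """Entrywise mixture of education-specific transition matrices.

    All inputs must share the age grid, the period, and the non-education
    part of the subgroup context. The result is the counterfactual matrix
    for a population whose education distribution is ``weights``.
    """
    if set(probs_by_education) != set(EDUCATION_LEVELS):
        raise ValueError(f"need one TransitionProbs per level in {EDUCATION_LEVELS}")
    items = [probs_by_education[e] for e in EDUCATION_LEVELS]
    ref = items[0]
    contexts = set()
    for tp in items:
        if not np.array_equal(tp.ages, ref.ages):
            raise ValueError("education-specific inputs are on different age grids")
        if tp.period != ref.period:
            raise ValueError("education-specific inputs are for different periods")
        contexts.add(tp.subgroup.split("/")[0])
    if len(contexts) > 1:
        raise ValueError(f"mixed non-education contexts: {sorted(contexts)}")
    mix = sum(
        weights[e] * probs_by_education[e].array for e in EDUCATION_LEVELS
    )
    # the dead identity row and the zero recovery entry are structural; pin
    # them exactly rather than leaving float-summation residue
    mix[:, 2, :] = (0.0, 0.0, 1.0)
    mix[:, 1, 0] = 0.0
    out = TransitionProbs(
        mix,
        ref.ages,
        period=ref.period,
        subgroup=f"{contexts.pop()}/edu-standardized",
    )
    return out.validate()
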