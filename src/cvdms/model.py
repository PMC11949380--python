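"""Model/Results front-end for the multistate burden analysis.

:class:`CVDMultistateModel` is constructed from a person-period panel (or
pre-aggregated transition counts) plus a stratification scheme; ``fit()``
estimates the per-origin multinomial logits and returns a
:class:`CVDMultistateResults` holding coefficients, standard errors and
convergence diagnostics, from which transition probabilities, burden-metric
tables and education-standardized counterfactual tables are derived.

    >>> model = CVDMultistateModel(table, scheme="by_gender")
    >>> res = model.fit()
    >>> res.summary()
    >>> res.metrics_table().df
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import PersonPeriodTable
from .estimation import (
    CovariateSpec,
    STRATIFICATION_SCHEMES,
    TransitionModel,
    TransitionProbs,
    aggregate_transitions,
    fit_stratified,
    predict_transition_probs,
)
from .reporting import MetricsTable, build_metrics_table
from .standardization import (
    EducationWeights,
    pooled_education_weights,
    standardize_transition_probs,
)
from .states import DEFAULT_GRID, EDUCATION_LEVELS, GENDERS, AgeGrid

__all__ = ["CVDMultistateModel", "CVDMultistateResults"]


class CVDMultistateModel:
    """Discrete-time illness-death model on a quarterly person-period panel.

    Parameters
    ----------
    data
        :class:`PersonPeriodTable`, a raw person-period DataFrame, or an
        aggregated count frame (with a ``count`` column).
    scheme
        ``"total"``, ``"by_gender"`` or ``"by_gender_education"`` — how many
        separate subpopulation models to fit. Stratifying variables never
        enter as covariates.
    covariates
        :class:`CovariateSpec`; defaults to age + age^2 + period dummies
        with age centered at 840 months and scaled by 120.
    """

    def __init__(
        self,
        data: PersonPeriodTable | pd.DataFrame,
        scheme: str = "total",
        covariates: CovariateSpec | None = None,
        grid: AgeGrid = DEFAULT_GRID,
    ) -> None:
        if scheme not in STRATIFICATION_SCHEMES:
            raise ValueError(
                f"unknown scheme {scheme!r}; choose one of {STRATIFICATION_SCHEMES}"
            )
        self.data = data
        self.scheme = scheme
        self.covariates = covariates or CovariateSpec()
        self.grid = grid

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CVDMultistateModel":
        data = df if "count" in df.columns else PersonPeriodTable(df)
        return cls(data, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "CVDMultistateModel":
        return cls(PersonPeriodTable.from_csv(path), **kwargs)

    def fit(self) -> "CVDMultistateResults":
        models = fit_stratified(
            self.data, scheme=self.scheme, covariate_spec=self.covariates, grid=self.grid
        )
        return CVDMultistateResults(model=self, models=models)


@dataclass
class CVDMultistateResults:
    """Fitted transition models and everything derived from them."""

    model: CVDMultistateModel
    models: dict[str, TransitionModel]

    # ----------------------------------------------------------- estimates
    @property
    def params(self) -> pd.DataFrame:
        """Long-format coefficients with standard errors and z-values."""
        rows = []
        for subgroup, tm in self.models.items():
            for origin, dests in tm.coef.items():
                for dest, beta in dests.items():
                    bse = tm.bse[origin][dest] if tm.bse else np.full_like(beta, np.nan)
                    for name, b, s in zip(tm.spec.columns, beta, bse):
                        rows.append(
                            {
                                "subgroup": subgroup,
                                "origin": origin,
                                "destination": dest,
                                "covariate": name,
                                "coef": b,
                                "se": s,
                                "z": b / s if s and np.isfinite(s) and s > 0 else np.nan,
                            }
                        )
        return pd.DataFrame(rows)

    @property
    def converged(self) -> bool:
        return all(
            info.get("converged", False)
            for tm in self.models.values()
            for info in tm.diagnostics.values()
        )

    def loglik(self) -> float:
        return sum(
            info["loglik"]
            for tm in self.models.values()
            for info in tm.diagnostics.values()
        )

    def summary(self) -> str:
        """Human-readable estimation summary."""
        lines = [
            "Discrete-time multistate (illness-death) transition model",
            f"scheme: {self.model.scheme} | subgroups: {len(self.models)} | "
            f"converged: {self.converged} | log-likelihood: {self.loglik():.2f}",
            f"age centered at {self.model.covariates.age_center:.0f} months, "
            f"scale {self.model.covariates.age_scale:.0f}; reference destination: stay",
            "",
        ]
        p = self.params
        with pd.option_context("display.float_format", "{:10.4f}".format):
            for (sg, origin, dest), sub in p.groupby(
                ["subgroup", "origin", "destination"], sort=False
            ):
                lines.append(f"[{sg}] {origin} -> {dest}")
                lines.append(
                    sub[["covariate", "coef", "se", "z"]].to_string(index=False)
                )
                lines.append("")
        return "\n".join(lines)

    # ----------------------------------------------------------- predictions
    def transition_probs(
        self, period: str, subgroup: str = "total"
    ) -> TransitionProbs:
        if subgroup not in self.models:
            raise KeyError(
                f"subgroup {subgroup!r} not fitted; have {sorted(self.models)}"
            )
        return predict_transition_probs(
            self.models[subgroup], grid=self.model.grid, period=period, subgroup=subgroup
        )

    def metrics_table(
        self, periods: list[str] | None = None, subgroups: list[str] | None = None
    ) -> MetricsTable:
        """Burden metrics for every fitted subgroup in every period."""
        periods = periods or list(self.model.covariates.periods)
        subgroups = subgroups or list(self.models)
        probs = [self.transition_probs(p, sg) for sg in subgroups for p in periods]
        return MetricsTable(
            build_metrics_table(probs).df, scheme=self.model.scheme
        )

    # ------------------------------------------------------- standardization
    def education_weights(self, gender: str) -> EducationWeights:
        """Education shares pooled over the full window, within a gender."""
        return pooled_education_weights(
            aggregate_transitions(self.model.data, grid=self.model.grid), gender=gender
        )

    def standardized_transition_probs(
        self, period: str, gender: str, weights: EducationWeights | None = None
    ) -> TransitionProbs:
        if self.model.scheme != "by_gender_education":
            raise ValueError(
                "education standardization requires scheme='by_gender_education'"
            )
        weights = weights or self.education_weights(gender)
        by_edu = {
            e: self.transition_probs(period, f"{gender}/{e}") for e in EDUCATION_LEVELS
        }
        return standardize_transition_probs(by_edu, weights)

    def standardized_metrics_table(
        self,
        periods: list[str] | None = None,
        weights: dict[str, EducationWeights] | None = None,
    ) -> MetricsTable:
        """Counterfactual per-gender metrics under a fixed education mix."""
        periods = periods or list(self.model.covariates.periods)
        probs = []
        for g in GENDERS:
            w = weights[g] if weights else self.education_weights(g)
            probs += [
                self.standardized_transition_probs(p, g, weights=w) for p in periods
            ]
        return MetricsTable(
            build_metrics_table(probs).df,
            scheme=self.model.scheme,
            standardized=True,
        )
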