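"""Multinomial-logit estimation of quarterly transition probabilities.

For each transient origin state ``i`` and destination ``j`` the per-step
transition probability is modelled as

    log( p_ij / p_i,stay ) = a_ij + b1_ij * age + b2_ij * age^2 + d_ij' Period

where age enters centered and scaled (default center 840 months, scale 120
months) and the five-year period variable is dummy-coded with the first
period as reference. The reference destination for every origin is the
"stay" state (FREE -> FREE, CVD -> CVD); predicted probabilities are
invariant to this choice. Models are fitted separately per origin state: the
multinomial likelihood factorizes over origins, so per-origin fits are the
joint maximum-likelihood estimates.

Fitting operates on aggregated covariate cells (age x period x stratum) with
multinomial counts, so register-scale inputs of tens of millions of
person-period rows collapse to a few thousand weighted observations. The
solver is a damped Newton-Raphson on the exact multinomial log-likelihood
with analytic gradient and Hessian; standard errors come from the observed
information matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import PersonPeriodTable
from .states import (
    CVD,
    DEAD,
    DEFAULT_GRID,
    EDUCATION_LEVELS,
    FREE,
    GENDERS,
    PERIODS,
    STATE_INDEX,
    STATE_SPACE,
    STATES,
    AgeGrid,
)

__all__ = [
    "CovariateSpec",
    "TransitionModel",
    "TransitionProbs",
    "SeparationError",
    "fit_transition_model",
    "fit_transitions",
    "fit_stratified",
    "predict_transition_probs",
    "multinomial_loglik",
]


class SeparationError(RuntimeError):
    """Raised when the multinomial likelihood diverges (perfect separation)."""


@dataclass(frozen=True)
class CovariateSpec:
    """Which covariates enter the transition model, and how age is scaled."""

    include_age: bool = True
    include_age2: bool = True
    include_period: bool = True
    age_center: float = 840.0
    age_scale: float = 120.0
    periods: tuple[str, ...] = PERIODS

    @property
    def columns(self) -> list[str]:
        cols = ["const"]
        if self.include_age:
            cols.append("age")
        if self.include_age2:
            cols.append("age2")
        if self.include_period:
            cols += [f"period[{p}]" for p in self.periods[1:]]
        return cols

    @property
    def n_params(self) -> int:
        return len(self.columns)

    def design(self, age_month: np.ndarray, period_idx: np.ndarray) -> np.ndarray:
        """Design matrix rows for given ages (months) and period indices."""
        age_month = np.asarray(age_month, dtype=float)
        period_idx = np.asarray(period_idx)
        x = (age_month - self.age_center) / self.age_scale
        cols = [np.ones_like(x)]
        if self.include_age:
            cols.append(x)
        if self.include_age2:
            cols.append(x * x)
        if self.include_period:
            for k in range(1, len(self.periods)):
                cols.append((period_idx == k).astype(float))
        return np.column_stack(cols)


# --------------------------------------------------------------------------
# model containers
# --------------------------------------------------------------------------


@dataclass
class TransitionModel:
    """Per-origin multinomial-logit coefficients for the illness-death chain.

    ``coef[origin][dest]`` holds the coefficient vector (ordered as
    ``spec.columns``) of destination ``dest`` relative to the reference
    destination, which is always the stay state (= origin). ``bse`` mirrors
    ``coef`` with estimated standard errors when the model was fitted.
    """

    spec: CovariateSpec = field(default_factory=CovariateSpec)
    coef: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    bse: dict[str, dict[str, np.ndarray]] | None = None
    diagnostics: dict[str, dict] = field(default_factory=dict)
    subgroup: str = "total"

    def __post_init__(self) -> None:
        for origin, dests in self.coef.items():
            allowed = set(STATE_SPACE.destinations(origin)) - {origin}
            if set(dests) != allowed:
                raise ValueError(
                    f"origin {origin!r}: destinations {sorted(dests)} != "
                    f"allowed non-reference destinations {sorted(allowed)}"
                )
            for dest, beta in dests.items():
                beta = np.asarray(beta, dtype=float)
                if beta.shape != (self.spec.n_params,):
                    raise ValueError(
                        f"{origin}->{dest}: expected {self.spec.n_params} "
                        f"coefficients, got {beta.shape}"
                    )
                if not np.all(np.isfinite(beta)):
                    raise ValueError(f"{origin}->{dest}: non-finite coefficients")
                dests[dest] = beta

    @property
    def origins(self) -> tuple[str, ...]:
        return tuple(self.coef)

    def destinations(self, origin: str) -> tuple[str, ...]:
        """Non-reference destinations for an origin, in state order."""
        return tuple(s for s in STATES if s in self.coef[origin])

    def linear_predictors(
        self, origin: str, age_month: np.ndarray, period: str
    ) -> dict[str, np.ndarray]:
        if period not in self.spec.periods:
            raise ValueError(f"unknown period label {period!r}")
        period_idx = np.full(np.shape(age_month), self.spec.periods.index(period))
        X = self.spec.design(np.asarray(age_month), period_idx)
        return {d: X @ self.coef[origin][d] for d in self.destinations(origin)}

    def step_probs(
        self, origin: str, age_month: np.ndarray, period: str
    ) -> dict[str, np.ndarray]:
        """Per-step probabilities for every allowed destination (incl. stay)."""
        eta = self.linear_predictors(origin, age_month, period)
        dests = list(eta)
        E = np.stack([eta[d] for d in dests], axis=-1)
        # softmax against the implicit 0 linear predictor of the stay state
        m = np.maximum(E.max(axis=-1), 0.0)
        num = np.exp(E - m[..., None])
        denom = np.exp(-m) + num.sum(axis=-1)
        probs = {d: num[..., k] / denom for k, d in enumerate(dests)}
        probs[origin] = np.exp(-m) / denom
        return probs

    def merged_with(self, other: "TransitionModel") -> "TransitionModel":
        """Combine per-origin fits that share a covariate spec."""
        if other.spec != self.spec:
            raise ValueError("cannot merge models with different covariate specs")
        overlap = set(self.coef) & set(other.coef)
        if overlap:
            raise ValueError(f"both models fit origins {sorted(overlap)}")
        bse = None
        if self.bse is not None and other.bse is not None:
            bse = {**self.bse, **other.bse}
        return TransitionModel(
            spec=self.spec,
            coef={**self.coef, **other.coef},
            bse=bse,
            diagnostics={**self.diagnostics, **other.diagnostics},
            subgroup=self.subgroup,
        )

    # ------------------------------------------------------------ serialization
    def to_dict(self) -> dict:
        out = {
            "spec": {
                "include_age": self.spec.include_age,
                "include_age2": self.spec.include_age2,
                "include_period": self.spec.include_period,
                "age_center": self.spec.age_center,
                "age_scale": self.spec.age_scale,
                "periods": list(self.spec.periods),
            },
            "subgroup": self.subgroup,
            "coef": {
                o: {d: list(map(float, b)) for d, b in dests.items()}
                for o, dests in self.coef.items()
            },
            "diagnostics": self.diagnostics,
        }
        if self.bse is not None:
            out["bse"] = {
                o: {d: list(map(float, b)) for d, b in dests.items()}
                for o, dests in self.bse.items()
            }
        return out

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionModel":
        spec = CovariateSpec(
            include_age=d["spec"]["include_age"],
            include_age2=d["spec"]["include_age2"],
            include_period=d["spec"]["include_period"],
            age_center=d["spec"]["age_center"],
            age_scale=d["spec"]["age_scale"],
            periods=tuple(d["spec"]["periods"]),
        )
        bse = None
        if "bse" in d:
            bse = {
                o: {dd: np.asarray(b, dtype=float) for dd, b in dests.items()}
                for o, dests in d["bse"].items()
            }
        return cls(
            spec=spec,
            coef={
                o: {dd: np.asarray(b, dtype=float) for dd, b in dests.items()}
                for o, dests in d["coef"].items()
            },
            bse=bse,
            diagnostics=d.get("diagnostics", {}),
            subgroup=d.get("subgroup", "total"),
        )

    @classmethod
    def from_json(cls, path) -> "TransitionModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class TransitionProbs:
    """Age-indexed per-step transition matrix for one period x subgroup.

    ``array[t, i, j]`` is the probability of moving from state ``i`` to state
    ``j`` over the interval starting at ``ages[t]`` months. Rows are
    stochastic, forbidden moves are exactly zero, and the dead row is the
    identity row.
    """

    array: np.ndarray
    ages: np.ndarray
    period: str
    subgroup: str = "total"

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array, dtype=float)
        self.ages = np.asarray(self.ages, dtype=np.int64)
        if self.array.shape != (len(self.ages), 3, 3):
            raise ValueError("array must have shape (n_ages, 3, 3)")

    def validate(self, atol: float = 1e-12) -> "TransitionProbs":
        a = self.array
        if np.any(a < -atol) or np.any(a > 1 + atol):
            raise ValueError("probabilities outside [0, 1]")
        if np.max(np.abs(a.sum(axis=2) - 1.0)) > atol:
            raise ValueError("origin rows must sum to 1")
        i_cvd, i_dead = STATE_INDEX[CVD], STATE_INDEX[DEAD]
        if np.any(a[:, i_cvd, STATE_INDEX[FREE]] != 0.0):
            raise ValueError("recovery probability must be exactly zero")
        if np.any(a[:, i_dead, :] != np.array([0.0, 0.0, 1.0])):
            raise ValueError("dead row must be the identity row")
        return self

    def prob(self, origin: str, dest: str) -> np.ndarray:
        return self.array[:, STATE_INDEX[origin], STATE_INDEX[dest]]

    @property
    def n_intervals(self) -> int:
        return len(self.ages)

    @classmethod
    def constant(
        cls,
        p_free_cvd: float,
        p_free_dead: float,
        p_cvd_dead: float,
        grid: AgeGrid = DEFAULT_GRID,
        period: str = PERIODS[0],
        subgroup: str = "synthetic",
    ) -> "TransitionProbs":
        """Age-constant chain; handy for closed-form geometric checks."""
        n = grid.n_intervals
        a = np.zeros((n, 3, 3))
        a[:, 0, 1] = p_free_cvd
        a[:, 0, 2] = p_free_dead
        a[:, 0, 0] = 1.0 - p_free_cvd - p_free_dead
        a[:, 1, 2] = p_cvd_dead
        a[:, 1, 1] = 1.0 - p_cvd_dead
        a[:, 2, 2] = 1.0
        return cls(a, grid.interval_starts, period=period, subgroup=subgroup)

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, origin in enumerate(STATES):
            for j, dest in enumerate(STATES):
                rows.append(
                    pd.DataFrame(
                        {
                            "age_month": self.ages,
                            "origin": origin,
                            "destination": dest,
                            "probability": self.array[:, i, j],
                            "period": self.period,
                            "subgroup": self.subgroup,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TransitionProbs":
        period = df["period"].iloc[0]
        subgroup = df["subgroup"].iloc[0]
        ages = np.sort(df["age_month"].unique())
        a = np.zeros((len(ages), 3, 3))
        pivot = df.pivot_table(
            index="age_month", columns=["origin", "destination"], values="probability"
        ).reindex(ages)
        for i, origin in enumerate(STATES):
            for j, dest in enumerate(STATES):
                if (origin, dest) in pivot.columns:
                    a[:, i, j] = pivot[(origin, dest)].to_numpy()
        return cls(a, ages, period=period, subgroup=subgroup)

    @classmethod
    def from_csv(cls, path) -> "TransitionProbs":
        return cls.from_frame(pd.read_csv(path))


# --------------------------------------------------------------------------
# aggregation
# --------------------------------------------------------------------------


def aggregate_transitions(
    data: PersonPeriodTable | pd.DataFrame,
    grid: AgeGrid = DEFAULT_GRID,
    periods: tuple[str, ...] = PERIODS,
) -> pd.DataFrame:
    """Collapse person-period rows to multinomial counts per covariate cell.

    Returns a frame with one row per observed
    (age_month, period, gender, education, state_now, state_next) cell and a
    ``count`` column. Frames that already carry a ``count`` column pass
    through unchanged.
    """
    df = data.df if isinstance(data, PersonPeriodTable) else data
    if "count" in df.columns:
        return df
    if df.empty:
        return df.assign(count=pd.Series(dtype=np.int64))
    age_idx = (df["age_month"].to_numpy(np.int64) - grid.start_month) // grid.step_months
    p_idx = pd.Categorical(df["period"], categories=list(periods)).codes.astype(np.int64)
    g_idx = pd.Categorical(df["gender"], categories=list(GENDERS)).codes.astype(np.int64)
    e_idx = pd.Categorical(
        df["education"], categories=list(EDUCATION_LEVELS)
    ).codes.astype(np.int64)
    o_idx = pd.Categorical(df["state_now"], categories=list(STATES)).codes.astype(np.int64)
    d_idx = pd.Categorical(df["state_next"], categories=list(STATES)).codes.astype(np.int64)
    dims = (grid.n_intervals, len(periods), 2, 3, 3, 3)
    key = age_idx
    for idx, dim in zip((p_idx, g_idx, e_idx, o_idx, d_idx), dims[1:]):
        key = key * dim + idx
    counts = np.bincount(key, minlength=int(np.prod(dims)))
    nz = np.flatnonzero(counts)
    unravel = np.unravel_index(nz, dims)
    return pd.DataFrame(
        {
            "age_month": grid.start_month + unravel[0] * grid.step_months,
            "period": np.asarray(periods)[unravel[1]],
            "gender": np.asarray(GENDERS)[unravel[2]],
            "education": np.asarray(EDUCATION_LEVELS)[unravel[3]],
            "state_now": np.asarray(STATES)[unravel[4]],
            "state_next": np.asarray(STATES)[unravel[5]],
            "count": counts[nz],
        }
    )


# --------------------------------------------------------------------------
# weighted multinomial-logit MLE
# --------------------------------------------------------------------------


def multinomial_loglik(X: np.ndarray, Y: np.ndarray, beta: np.ndarray) -> float:
    """Multinomial log-likelihood at ``beta`` for counts ``Y``.

    ``Y[:, 0]`` counts the reference destination; ``beta`` has shape
    (n_dest - 1, n_params), matching ``Y[:, 1:]``.
    """
    eta = X @ beta.T  # (n, K-1)
    m = np.maximum(eta.max(axis=1), 0.0)
    lse = m + np.log(np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1))
    n_tot = Y.sum(axis=1)
    return float((Y[:, 1:] * eta).sum() - (n_tot * lse).sum())


def _newton_mnlogit(
    X: np.ndarray,
    Y: np.ndarray,
    colnames: list[str],
    max_iter: int = 100,
    tol: float = 1e-9,
    divergence_bound: float = 30.0,
):
    """Damped Newton-Raphson for the weighted multinomial logit.

    Returns (beta, bse, info). Raises :class:`SeparationError` when a
    coefficient runs away, naming the offending covariate.
    """
    n, p = X.shape
    k = Y.shape[1] - 1  # free destinations
    beta = np.zeros((k, p))
    n_tot = Y.sum(axis=1).astype(float)
    ll = multinomial_loglik(X, Y, beta)
    converged = False
    for it in range(max_iter):
        eta = X @ beta.T
        m = np.maximum(eta.max(axis=1), 0.0)
        num = np.exp(eta - m[:, None])
        denom = np.exp(-m) + num.sum(axis=1)
        P = num / denom[:, None]  # (n, k)
        grad = np.empty(k * p)
        for j in range(k):
            grad[j * p : (j + 1) * p] = X.T @ (Y[:, j + 1] - n_tot * P[:, j])
        H = np.empty((k * p, k * p))
        for j in range(k):
            for l in range(k):
                w = n_tot * P[:, j] * ((j == l) - P[:, l])
                H[j * p : (j + 1) * p, l * p : (l + 1) * p] = X.T @ (w[:, None] * X)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as err:
            raise SeparationError(
                "singular information matrix; data cannot identify "
                f"coefficients for covariates {colnames}"
            ) from err
        # damped update: halve until the log-likelihood does not decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step.reshape(k, p)
            ll_new = multinomial_loglik(X, Y, cand)
            if ll_new >= ll - 1e-10:
                break
            scale *= 0.5
        beta = cand
        if np.max(np.abs(beta)) > divergence_bound:
            j, c = np.unravel_index(np.argmax(np.abs(beta)), beta.shape)
            raise SeparationError(
                f"likelihood diverging (|coefficient| > {divergence_bound}) for "
                f"covariate {colnames[c]!r}: probable perfect separation"
            )
        delta = np.max(np.abs(scale * step))
        ll = ll_new
        if delta < tol and np.max(np.abs(grad)) < 1e-6 * max(1.0, n_tot.sum()):
            converged = True
            break
    cov = np.linalg.inv(H)
    bse = np.sqrt(np.diag(cov)).reshape(k, p)
    info = {
        "converged": bool(converged),
        "iterations": it + 1,
        "loglik": ll,
        "n_obs": float(n_tot.sum()),
        "max_grad": float(np.max(np.abs(grad))),
    }
    if not converged:
        warnings.warn("multinomial logit did not fully converge", RuntimeWarning)
    return beta, bse, info


def fit_transition_model(
    data: PersonPeriodTable | pd.DataFrame,
    origin: str,
    covariate_spec: CovariateSpec | None = None,
    grid: AgeGrid = DEFAULT_GRID,
    subgroup: str = "total",
) -> TransitionModel:
    """Fit the multinomial logit of ``state_next`` for one origin state.

    ``data`` is either a person-period table or a pre-aggregated count frame
    from :func:`aggregate_transitions`. For origin CVD the model degenerates
    to a binary logit (stay vs die). Returns a :class:`TransitionModel`
    carrying this origin's coefficients, standard errors and convergence
    diagnostics.
    """
    spec = covariate_spec or CovariateSpec()
    if origin not in (FREE, CVD):
        raise ValueError(f"origin must be a transient state, got {origin!r}")
    cells = aggregate_transitions(data, grid=grid, periods=spec.periods)
    cells = cells[cells["state_now"] == origin]
    if cells.empty or cells["count"].sum() == 0:
        raise ValueError(f"no rows with state_now = {origin!r} to fit on")
    dests = [origin] + [
        s for s in STATES if s in STATE_SPACE.destinations(origin) and s != origin
    ]
    p_idx = pd.Categorical(cells["period"], categories=list(spec.periods)).codes
    covkey = pd.MultiIndex.from_arrays([cells["age_month"], pd.Index(p_idx)])
    codes, uniques = pd.factorize(covkey, sort=True)
    n_cells = len(uniques)
    Y = np.zeros((n_cells, len(dests)))
    d_pos = cells["state_next"].map({d: i for i, d in enumerate(dests)}).to_numpy()
    np.add.at(Y, (codes, d_pos), cells["count"].to_numpy(float))
    ages = np.asarray([u[0] for u in uniques], dtype=float)
    pidx = np.asarray([u[1] for u in uniques])
    X = spec.design(ages, pidx)
    beta, bse, info = _newton_mnlogit(X, Y, spec.columns)
    coef = {origin: {d: beta[j] for j, d in enumerate(dests[1:])}}
    bse_d = {origin: {d: bse[j] for j, d in enumerate(dests[1:])}}
    return TransitionModel(
        spec=spec,
        coef=coef,
        bse=bse_d,
        diagnostics={origin: info},
        subgroup=subgroup,
    )


def fit_transitions(
    data: PersonPeriodTable | pd.DataFrame,
    covariate_spec: CovariateSpec | None = None,
    grid: AgeGrid = DEFAULT_GRID,
    subgroup: str = "total",
) -> TransitionModel:
    """Fit both transient origins (FREE and CVD) and merge into one model."""
    m_free = fit_transition_model(data, FREE, covariate_spec, grid, subgroup)
    m_cvd = fit_transition_model(data, CVD, covariate_spec, grid, subgroup)
    return m_free.merged_with(m_cvd)


STRATIFICATION_SCHEMES = ("total", "by_gender", "by_gender_education")


def fit_stratified(
    data: PersonPeriodTable | pd.DataFrame,
    scheme: str = "total",
    covariate_spec: CovariateSpec | None = None,
    grid: AgeGrid = DEFAULT_GRID,
) -> dict[str, TransitionModel]:
    """Fit transition models separately per subpopulation.

    ``total`` fits one model on everyone; ``by_gender`` two models (gender is
    then not a covariate); ``by_gender_education`` six models, one per
    gender x education cell. Covariates inside each stratum are always
    age, age^2 and period only — the stratifying variables never enter.
    """
    if scheme not in STRATIFICATION_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose {STRATIFICATION_SCHEMES}")
    cells = aggregate_transitions(data, grid=grid)
    if scheme == "total":
        strata = {"total": cells}
    elif scheme == "by_gender":
        strata = {g: cells[cells["gender"] == g] for g in GENDERS}
    else:
        strata = {
            f"{g}/{e}": cells[(cells["gender"] == g) & (cells["education"] == e)]
            for g in GENDERS
            for e in EDUCATION_LEVELS
        }
    out = {}
    for label, sub in strata.items():
        if sub.empty:
            raise ValueError(f"stratum {label!r} has no observations")
        out[label] = fit_transitions(sub, covariate_spec, grid, subgroup=label)
    return out


def predict_transition_probs(
    model: TransitionModel,
    grid: AgeGrid = DEFAULT_GRID,
    period: str = PERIODS[0],
    subgroup: str | None = None,
) -> TransitionProbs:
    """Evaluate the fitted model on every grid interval for one period.

    Activating a period means setting that period's dummy to 1 and all
    others to 0 (the first period is the all-zero reference pattern).
    """
    if period not in model.spec.periods:
        raise ValueError(f"unknown period label {period!r}")
    missing = {FREE, CVD} - set(model.origins)
    if missing:
        raise ValueError(f"model lacks fitted origins: {sorted(missing)}")
    ages = grid.interval_starts
    a = np.zeros((len(ages), 3, 3))
    for origin in (FREE, CVD):
        probs = model.step_probs(origin, ages, period)
        for dest, pr in probs.items():
            a[:, STATE_INDEX[origin], STATE_INDEX[dest]] = pr
    a[:, STATE_INDEX[DEAD], STATE_INDEX[DEAD]] = 1.0
    tp = TransitionProbs(
        a, ages, period=period, subgroup=subgroup or model.subgroup
    )
    return tp.validate()
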