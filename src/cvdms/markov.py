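"""Markov-chain functionals: occupancy, lifetime risk, onset age, expectancies.

All quantities are period (synthetic-cohort) measures: a cohort starting
CVD-free at exactly 480 months is pushed through the age-specific quarterly
transition matrices of a single period regime, as if it lived its whole life
under that period's conditions.

Conventions, pinned by tests:

* occupancy is counted at interval starts; each occupied start contributes
  0.25 years of exposure;
* the horizon is truncated at 1,200 months — survivors at age 100 contribute
  no further person-years (downward bias at extreme ages);
* a first CVD transition occurring in the interval [a, a+3) is assigned onset
  age a+3 months (the destination grid point, where the event is first
  observed);
* undefined conditional quantities (e.g. mean onset age when lifetime risk
  is zero) return NaN with a warning rather than raising, so batch tables
  never abort.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .estimation import TransitionProbs
from .states import CVD, DEAD, FREE, STATE_INDEX

__all__ = [
    "OccupancyCurve",
    "FirstPassageDistribution",
    "MetricsRow",
    "occupancy_forward",
    "first_passage_onset",
    "lifetime_risk",
    "mean_onset_age",
    "state_expectancies",
    "conditional_tle",
    "metrics_row",
    "microsim_metrics",
]

TLE65_START_MONTH = 780  # age 65


@dataclass
class OccupancyCurve:
    """State-occupancy probabilities over the grid, given a start condition."""

    ages: np.ndarray  # grid points (months), start_age .. end
    probs: np.ndarray  # (n_ages, 3)
    start_state: str
    start_age: int

    def occupancy(self, state: str) -> np.ndarray:
        return self.probs[:, STATE_INDEX[state]]


@dataclass
class FirstPassageDistribution:
    """Distribution of the interval in which CVD is first entered."""

    onset_ages: np.ndarray  # destination grid points (months)
    mass: np.ndarray  # P(first FREE->CVD move lands on that grid point)
    start_age: int

    @property
    def total_mass(self) -> float:
        """Probability of ever entering CVD — the lifetime risk."""
        return float(self.mass.sum())


def _start_index(probs: TransitionProbs, start_age: int) -> int:
    ages = probs.ages
    hits = np.flatnonzero(ages == start_age)
    if len(hits) == 0:
        raise ValueError(
            f"start age {start_age} months is not an interval start on the grid "
            f"({ages[0]}..{ages[-1]} by {ages[1] - ages[0] if len(ages) > 1 else '?'})"
        )
    return int(hits[0])


def occupancy_forward(
    probs: TransitionProbs, start_state: str = FREE, start_age: int = 480
) -> OccupancyCurve:
    """Forward recursion: row vector times transition matrix, age by age."""
    if start_state not in (FREE, CVD):
        raise ValueError(f"start state must be transient, got {start_state!r}")
    t0 = _start_index(probs, start_age)
    step = int(probs.ages[1] - probs.ages[0]) if len(probs.ages) > 1 else 3
    n_steps = probs.n_intervals - t0
    out = np.zeros((n_steps + 1, 3))
    v = np.zeros(3)
    v[STATE_INDEX[start_state]] = 1.0
    out[0] = v
    for k in range(n_steps):
        v = v @ probs.array[t0 + k]
        out[k + 1] = v
    ages = np.concatenate([probs.ages[t0:], [probs.ages[-1] + step]])
    return OccupancyCurve(ages=ages, probs=out, start_state=start_state, start_age=start_age)


def first_passage_onset(
    probs: TransitionProbs, start_age: int = 480
) -> FirstPassageDistribution:
    """First-passage distribution of CVD onset for a cohort starting FREE.

    Because CVD entry is irreversible, occupying FREE at age a means never
    having left it, so the onset mass in the interval starting at a is
    P(FREE at a) * p(FREE->CVD at a).
    """
    occ = occupancy_forward(probs, FREE, start_age)
    t0 = _start_index(probs, start_age)
    still_free = occ.occupancy(FREE)[:-1]  # at each interval start
    p_onset = probs.prob(FREE, CVD)[t0:]
    step = int(probs.ages[1] - probs.ages[0]) if len(probs.ages) > 1 else 3
    return FirstPassageDistribution(
        onset_ages=probs.ages[t0:] + step,
        mass=still_free * p_onset,
        start_age=start_age,
    )


def lifetime_risk(probs: TransitionProbs, start_age: int = 480) -> float:
    """Probability of ever experiencing CVD before death or the horizon."""
    return first_passage_onset(probs, start_age).total_mass


def mean_onset_age(probs: TransitionProbs, start_age: int = 480) -> float:
    """Mean age (years) at CVD onset, conditional on onset occurring.

    Returns NaN with a warning when the lifetime risk is zero.
    """
    fp = first_passage_onset(probs, start_age)
    if fp.total_mass <= 0.0:
        warnings.warn("zero lifetime risk: mean onset age is undefined", RuntimeWarning)
        return math.nan
    return float((fp.mass * (fp.onset_ages / 12.0)).sum() / fp.total_mass)


def state_expectancies(
    probs: TransitionProbs, start_age: int = 480
) -> tuple[float, float, float, float]:
    """(e_free, e_cvd, tle, pct_free) in years for a cohort starting FREE.

    Each state expectancy is 0.25 years times the summed occupancy
    probability over interval starts up to the 1,200-month horizon.
    """
    occ = occupancy_forward(probs, FREE, start_age)
    step_years = (occ.ages[1] - occ.ages[0]) / 12.0
    e_free = float(occ.occupancy(FREE)[:-1].sum() * step_years)
    e_cvd = float(occ.occupancy(CVD)[:-1].sum() * step_years)
    tle = e_free + e_cvd
    pct_free = 100.0 * e_free / tle if tle > 0 else math.nan
    return e_free, e_cvd, tle, pct_free


def conditional_tle(
    probs: TransitionProbs,
    start_age: int = TLE65_START_MONTH,
    start_state: str = CVD,
) -> float:
    """Expected remaining years alive from ``start_age``, given ``start_state``.

    Default arguments give total life expectancy at age 65 for those with
    CVD, under the same interval-start occupancy counting and 1,200-month
    truncation as :func:`state_expectancies`.
    """
    occ = occupancy_forward(probs, start_state, start_age)
    step_years = (occ.ages[1] - occ.ages[0]) / 12.0
    alive = 1.0 - occ.occupancy(DEAD)
    return float(alive[:-1].sum() * step_years)


@dataclass
class MetricsRow:
    """One period x subgroup row of burden metrics.

    Lifetime risk is a proportion; onset and expectancies are in years;
    ``pct_free`` is the percentage of total life expectancy spent CVD-free.
    """

    period: str
    subgroup: str
    lifetime_risk: float
    onset_age_mean: float
    e_free: float
    e_cvd: float
    tle: float
    pct_free: float
    tle65_cvd: float
    se: dict[str, float] = field(default_factory=dict)

    def validate(self, horizon_years: float = 60.0) -> "MetricsRow":
        if abs(self.e_free + self.e_cvd - self.tle) > 1e-9:
            raise ValueError("e_free + e_cvd must equal tle")
        for name in ("e_free", "e_cvd", "tle"):
            v = getattr(self, name)
            if not (0.0 <= v <= horizon_years + 1e-9):
                raise ValueError(f"{name}={v} outside [0, horizon]")
        if self.tle > 0 and abs(self.pct_free - 100.0 * self.e_free / self.tle) > 1e-6:
            raise ValueError("pct_free inconsistent with e_free / tle")
        return self

    def to_dict(self) -> dict:
        return {
            "period": self.period,
            "subgroup": self.subgroup,
            "lifetime_risk": self.lifetime_risk,
            "onset_age_mean": self.onset_age_mean,
            "e_free": self.e_free,
            "e_cvd": self.e_cvd,
            "tle": self.tle,
            "pct_free": self.pct_free,
            "tle65_cvd": self.tle65_cvd,
        }


def metrics_row(probs: TransitionProbs, start_age: int = 480) -> MetricsRow:
    """Compute the full metric set from one transition-probability array."""
    e_free, e_cvd, tle, pct_free = state_expectancies(probs, start_age)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        onset = mean_onset_age(probs, start_age)
    return MetricsRow(
        period=probs.period,
        subgroup=probs.subgroup,
        lifetime_risk=lifetime_risk(probs, start_age),
        onset_age_mean=onset,
        e_free=e_free,
        e_cvd=e_cvd,
        tle=tle,
        pct_free=pct_free,
        tle65_cvd=conditional_tle(probs),
    ).validate()


# --------------------------------------------------------------------------
# microsimulation oracle
# --------------------------------------------------------------------------


def _simulate_cohort(
    probs: TransitionProbs, n: int, rng: np.random.Generator, start_state: str, t0: int
):
    """Simulate n trajectories from interval index t0; returns per-person
    (ever_cvd, onset_age_month[NaN if none], quarters_free, quarters_cvd)."""
    n_int = probs.n_intervals
    state = np.full(n, STATE_INDEX[start_state], dtype=np.int8)
    ever = state == STATE_INDEX[CVD]
    onset = np.full(n, np.nan)
    q_free = np.zeros(n, dtype=np.int64)
    q_cvd = np.zeros(n, dtype=np.int64)
    i_free, i_cvd, i_dead = (STATE_INDEX[s] for s in (FREE, CVD, DEAD))
    for t in range(t0, n_int):
        u = rng.random(n)
        free = state == i_free
        cvd = state == i_cvd
        q_free += free
        q_cvd += cvd
        p = probs.array[t]
        if free.any():
            uf = u[free]
            nxt = np.where(
                uf < p[i_free, i_cvd],
                i_cvd,
                np.where(uf < p[i_free, i_cvd] + p[i_free, i_dead], i_dead, i_free),
            ).astype(np.int8)
            new_onset = free.copy()
            new_onset[free] = nxt == i_cvd
            onset[new_onset] = probs.ages[t] + (
                probs.ages[1] - probs.ages[0] if len(probs.ages) > 1 else 3
            )
            ever |= new_onset
            state[free] = nxt
        if cvd.any():
            state[cvd] = np.where(u[cvd] < p[i_cvd, i_dead], i_dead, i_cvd).astype(np.int8)
    return ever, onset, q_free, q_cvd


def microsim_metrics(probs: TransitionProbs, n: int, seed: int) -> MetricsRow:
    """Estimate every metric by simulating individual trajectories.

    Independent oracle for the matrix functionals: n trajectories start FREE
    at 480 months (plus a second cohort starting CVD at 780 months for the
    conditional life expectancy), and each metric is computed empirically
    with the same counting conventions. The returned row carries Monte-Carlo
    standard errors in ``row.se``. Reproducible given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    step_years = (probs.ages[1] - probs.ages[0]) / 12.0 if len(probs.ages) > 1 else 0.25
    ever, onset, q_free, q_cvd = _simulate_cohort(probs, n, rng, FREE, 0)
    ltr = float(ever.mean())
    onset_obs = onset[~np.isnan(onset)] / 12.0
    if len(onset_obs):
        onset_mean = float(onset_obs.mean())
        onset_se = float(onset_obs.std(ddof=1) / math.sqrt(len(onset_obs))) if len(onset_obs) > 1 else math.nan
    else:
        warnings.warn("no simulated onsets: mean onset age undefined", RuntimeWarning)
        onset_mean, onset_se = math.nan, math.nan
    yrs_free = q_free * step_years
    yrs_cvd = q_cvd * step_years
    yrs_tot = yrs_free + yrs_cvd
    e_free, e_cvd, tle = float(yrs_free.mean()), float(yrs_cvd.mean()), float(yrs_tot.mean())
    # second cohort: alive-with-CVD at age 65
    t65 = _start_index(probs, TLE65_START_MONTH)
    _, _, qf65, qc65 = _simulate_cohort(probs, n, rng, CVD, t65)
    yrs65 = (qf65 + qc65) * step_years
    pct_free = 100.0 * e_free / tle if tle > 0 else math.nan
    # delta-method SE for the ratio of means e_free / tle
    if tle > 0:
        g = np.column_stack([yrs_free, yrs_tot])
        cov = np.cov(g, rowvar=False) / n
        d = np.array([100.0 / tle, -100.0 * e_free / tle**2])
        pct_se = float(math.sqrt(max(d @ cov @ d, 0.0)))
    else:
        pct_se = math.nan
    se = {
        "lifetime_risk": math.sqrt(max(ltr * (1 - ltr), 0.0) / n),
        "onset_age_mean": onset_se,
        "e_free": float(yrs_free.std(ddof=1) / math.sqrt(n)),
        "e_cvd": float(yrs_cvd.std(ddof=1) / math.sqrt(n)),
        "tle": float(yrs_tot.std(ddof=1) / math.sqrt(n)),
        "pct_free": pct_se,
        "tle65_cvd": float(yrs65.std(ddof=1) / math.sqrt(n)),
    }
    return MetricsRow(
        period=probs.period,
        subgroup=probs.subgroup,
        lifetime_risk=ltr,
        onset_age_mean=onset_mean,
        e_free=e_free,
        e_cvd=e_cvd,
        tle=tle,
        pct_free=pct_free,
        tle65_cvd=float(yrs65.mean()),
        se=se,
    )
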