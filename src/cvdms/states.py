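"""State space and age grid for the discrete-time illness-death model.

The model distinguishes three states — CVD-free, CVD, and dead — observed on
a quarterly age grid running from 480 to 1,200 months (ages 40-100 years).
CVD entry is irreversible and death is the single absorbing state, so the
allowed one-step moves are

    FREE -> FREE | CVD | DEAD
    CVD  -> CVD  | DEAD
    DEAD -> DEAD

Quarterly spacing is used so that first CVD events occurring shortly before
death are still captured as a visit to the CVD state rather than being
collapsed into a direct FREE -> DEAD move, which coarser (yearly) state
assignment would often do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FREE = "free"
CVD = "cvd"
DEAD = "dead"

#: canonical state order; indices into every transition matrix
STATES: tuple[str, str, str] = (FREE, CVD, DEAD)
STATE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STATES)}

#: five-year calendar period regimes
PERIODS: tuple[str, ...] = (
    "1996-2000",
    "2001-2005",
    "2006-2010",
    "2011-2015",
    "2016-2020",
)
GENDERS: tuple[str, str] = ("women", "men")
EDUCATION_LEVELS: tuple[str, str, str] = ("basic", "secondary", "tertiary")


@dataclass(frozen=True)
class StateSpace:
    """Three-state illness-death state space with a single absorbing state."""

    states: tuple[str, ...] = STATES
    transient: tuple[str, ...] = (FREE, CVD)
    absorbing: tuple[str, ...] = (DEAD,)
    allowed: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            FREE: (FREE, CVD, DEAD),
            CVD: (CVD, DEAD),
            DEAD: (DEAD,),
        }
    )

    def __post_init__(self) -> None:
        if len(self.absorbing) != 1:
            raise ValueError("exactly one absorbing state is required")
        absorbing = self.absorbing[0]
        if self.allowed[absorbing] != (absorbing,):
            raise ValueError("the absorbing state may only self-loop")
        if FREE in self.allowed.get(CVD, ()):
            raise ValueError("recovery (CVD -> FREE) is not allowed")
        if set(self.states) != set(self.transient) | set(self.absorbing):
            raise ValueError("states must partition into transient + absorbing")

    def is_allowed(self, origin: str, destination: str) -> bool:
        return destination in self.allowed[origin]

    def destinations(self, origin: str) -> tuple[str, ...]:
        return self.allowed[origin]


STATE_SPACE = StateSpace()

#: boolean mask M[i, j] = transition i -> j allowed
ALLOWED_MASK = np.array(
    [[STATE_SPACE.is_allowed(a, b) for b in STATES] for a in STATES], dtype=bool
)


@dataclass(frozen=True)
class AgeGrid:
    """Quarterly age grid in months.

    Defaults give 241 grid points (480, 483, ..., 1200) and 240 intervals of
    0.25 years each. Ages in years are months / 12.
    """

    start_month: int = 480
    end_month: int = 1200
    step_months: int = 3

    def __post_init__(self) -> None:
        if self.step_months <= 0:
            raise ValueError("step_months must be positive")
        if self.end_month <= self.start_month:
            raise ValueError("end_month must exceed start_month")
        if (self.end_month - self.start_month) % self.step_months:
            raise ValueError("(end - start) must be divisible by step")

    @property
    def n_points(self) -> int:
        return (self.end_month - self.start_month) // self.step_months + 1

    @property
    def n_intervals(self) -> int:
        return self.n_points - 1

    @property
    def step_years(self) -> float:
        return self.step_months / 12.0

    @property
    def points(self) -> np.ndarray:
        """All grid ages in months, including the terminal age."""
        return np.arange(
            self.start_month, self.end_month + 1, self.step_months, dtype=np.int64
        )

    @property
    def interval_starts(self) -> np.ndarray:
        """Ages in months at which each transition interval begins."""
        return self.points[:-1]

    def contains(self, age_month: int) -> bool:
        return (
            self.start_month <= age_month <= self.end_month
            and (age_month - self.start_month) % self.step_months == 0
        )

    def index_of(self, age_month: int) -> int:
        if not self.contains(age_month):
            raise ValueError(f"age {age_month} months is not on the grid")
        return (int(age_month) - self.start_month) // self.step_months

    @staticmethod
    def months_to_years(age_month) -> float:
        return np.asarray(age_month, dtype=float) / 12.0


DEFAULT_GRID = AgeGrid()
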