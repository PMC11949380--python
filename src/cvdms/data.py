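"""Person-period panel container.

The estimation input is one row per person per 3-month age step while the
person is alive, recording the state occupied at that age (``state_now``)
and the state occupied one step later (``state_next``). Rows where the
person is already dead are never stored; death appears only as a
``state_next`` value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .states import (
    CVD,
    DEAD,
    DEFAULT_GRID,
    EDUCATION_LEVELS,
    FREE,
    GENDERS,
    PERIODS,
    STATE_SPACE,
    AgeGrid,
)

COLUMNS = (
    "person_id",
    "age_month",
    "period",
    "gender",
    "education",
    "state_now",
    "state_next",
)


class InvalidTableError(ValueError):
    """Raised when a person-period table violates its schema or invariants."""


@dataclass
class PersonPeriodTable:
    """Quarterly person-period records with current and next state.

    Thin wrapper around a :class:`pandas.DataFrame` with the fixed column set
    ``person_id, age_month, period, gender, education, state_now, state_next``.
    """

    df: pd.DataFrame
    grid: AgeGrid = DEFAULT_GRID

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise InvalidTableError(f"missing columns: {missing}")
        self.df = self.df.loc[:, list(COLUMNS)]

    def __len__(self) -> int:
        return len(self.df)

    @property
    def empty(self) -> bool:
        return self.df.empty

    def validate(self) -> "PersonPeriodTable":
        """Check all table invariants; raise :class:`InvalidTableError` on failure.

        Checked: states and labels come from the documented vocabularies, no
        row has ``state_now = dead``, every (state_now, state_next) pair is an
        allowed move, ages sit on the grid strictly below its end, and each
        person's rows form a contiguous trajectory in which ``state_next`` at
        one age equals ``state_now`` at the next.
        """
        df = self.df
        if df.empty:
            return self
        for col, vocab in (
            ("period", PERIODS),
            ("gender", GENDERS),
            ("education", EDUCATION_LEVELS),
            ("state_now", STATE_SPACE.states),
            ("state_next", STATE_SPACE.states),
        ):
            bad = set(df[col].unique()) - set(vocab)
            if bad:
                raise InvalidTableError(f"unknown {col} labels: {sorted(bad)}")
        if (df["state_now"] == DEAD).any():
            raise InvalidTableError("rows with state_now = dead are not allowed")
        allowed = {
            (FREE, FREE),
            (FREE, CVD),
            (FREE, DEAD),
            (CVD, CVD),
            (CVD, DEAD),
        }
        pairs = set(map(tuple, df[["state_now", "state_next"]].drop_duplicates().values))
        if pairs - allowed:
            raise InvalidTableError(f"forbidden transitions present: {pairs - allowed}")
        ages = df["age_month"].to_numpy()
        if ages.max() >= self.grid.end_month:
            raise InvalidTableError("age_month must be strictly below the grid end")
        if ages.min() < self.grid.start_month:
            raise InvalidTableError("age_month below the grid start")
        if ((ages - self.grid.start_month) % self.grid.step_months).any():
            raise InvalidTableError("age_month values must lie on the grid")
        # per-person contiguity and state consistency
        s = df.sort_values(["person_id", "age_month"], kind="mergesort")
        same = s["person_id"].to_numpy()[1:] == s["person_id"].to_numpy()[:-1]
        age = s["age_month"].to_numpy()
        if not np.all(~same | (np.diff(age) == self.grid.step_months)):
            raise InvalidTableError("non-contiguous ages within a person trajectory")
        now = s["state_now"].to_numpy()
        nxt = s["state_next"].to_numpy()
        if not np.all(~same | (nxt[:-1] == now[1:])):
            raise InvalidTableError("state_next does not match the following state_now")
        return self

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grid: AgeGrid = DEFAULT_GRID) -> "PersonPeriodTable":
        df = pd.read_csv(
            path,
            dtype={
                "person_id": np.int64,
                "age_month": np.int64,
                "period": str,
                "gender": str,
                "education": str,
                "state_now": str,
                "state_next": str,
            },
        )
        return cls(df, grid=grid)

    @classmethod
    def empty_table(cls, grid: AgeGrid = DEFAULT_GRID) -> "PersonPeriodTable":
        df = pd.DataFrame(
            {
                "person_id": pd.Series(dtype=np.int64),
                "age_month": pd.Series(dtype=np.int64),
                "period": pd.Series(dtype=str),
                "gender": pd.Series(dtype=str),
                "education": pd.Series(dtype=str),
                "state_now": pd.Series(dtype=str),
                "state_next": pd.Series(dtype=str),
            }
        )
        return cls(df, grid=grid)
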