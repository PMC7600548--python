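"""Affective stimulus sets and balanced trial schedules.

Stimuli live in Russell's circumplex: a valence rating and an arousal rating,
each on [1, 9] with 5 the neutral point.  Ratings above/below 5 define the
high/low emotional state on each axis, and the two binary states define four
quadrants (HVHA, HVLA, LVHA, LVLA).  The generator draws normative-style
ratings uniformly inside each quadrant's rectangle, keeping a guard band
around the neutral value so state membership is never ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

QUADRANTS = ("HVHA", "HVLA", "LVHA", "LVLA")

#: half-width of the exclusion band around the neutral rating 5
NEUTRAL_GUARD = 0.1

RATING_MIN = 1.0
RATING_MAX = 9.0
NEUTRAL = 5.0


def quadrant_of(valence: float, arousal: float) -> str:
    """Quadrant label from the two binary states (>5 high, <5 low)."""
    v_high = valence > NEUTRAL
    a_high = arousal > NEUTRAL
    return {(True, True): "HVHA", (True, False): "HVLA",
            (False, True): "LVHA", (False, False): "LVLA"}[(v_high, a_high)]


@dataclass(frozen=True)
class StimulusSet:
    """A table of stimuli with normative valence/arousal ratings.

    Attributes
    ----------
    table : pandas.DataFrame
        Columns ``stimulus_id`` (int), ``valence``, ``arousal`` (float in
        [1, 9], never exactly 5) and ``quadrant`` (one of HVHA/HVLA/LVHA/LVLA).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"stimulus_id", "valence", "arousal", "quadrant"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"stimulus table missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ratings(self) -> pd.DataFrame:
        return self.table[["valence", "arousal"]]

    def rating_of(self, stimulus_id: int, axis: str) -> float:
        row = self.table.loc[self.table["stimulus_id"] == stimulus_id]
        if row.empty:
            raise KeyError(f"unknown stimulus_id {stimulus_id}")
        return float(row[axis].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StimulusSet":
        table = pd.read_csv(path)
        if "quadrant" not in table.columns:
            table["quadrant"] = [
                quadrant_of(v, a) for v, a in zip(table["valence"], table["arousal"])
            ]
        return cls(table=table)


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered (session_index, trial_index, stimulus_id) assignment.

    Every stimulus appears exactly once; sessions are equally long and each
    quadrant contributes equally to every session.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"session_index", "trial_index", "stimulus_id"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"schedule table missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_sessions(self) -> int:
        return int(self.table["session_index"].nunique())

    @property
    def stimulus_ids(self) -> np.ndarray:
        """Stimulus ids in presentation order (sessions concatenated)."""
        ordered = self.table.sort_values(["session_index", "trial_index"])
        return ordered["stimulus_id"].to_numpy()


# quadrant -> (valence interval, arousal interval), guard band excluded
_QUADRANT_BOXES = {
    "HVHA": ((NEUTRAL + NEUTRAL_GUARD, RATING_MAX), (NEUTRAL + NEUTRAL_GUARD, RATING_MAX)),
    "HVLA": ((NEUTRAL + NEUTRAL_GUARD, RATING_MAX), (RATING_MIN, NEUTRAL - NEUTRAL_GUARD)),
    "LVHA": ((RATING_MIN, NEUTRAL - NEUTRAL_GUARD), (NEUTRAL + NEUTRAL_GUARD, RATING_MAX)),
    "LVLA": ((RATING_MIN, NEUTRAL - NEUTRAL_GUARD), (RATING_MIN, NEUTRAL - NEUTRAL_GUARD)),
}


def generate_stimulus_set(n_per_quadrant: int = 40, seed: int = 0) -> StimulusSet:
    """Draw a quadrant-balanced stimulus set.

    Ratings are uniform within each quadrant's rectangle, excluding a ±0.1
    band around the neutral value 5 so that the >5 / <5 state split is exact.

    Parameters
    ----------
    n_per_quadrant : int
        Stimuli per quadrant; the default 40 gives the 160-picture design.
    seed : int
        Seeds a private generator; identical seeds give identical tables.
    """
    if n_per_quadrant < 1:
        raise ValueError(f"n_per_quadrant must be >= 1, got {n_per_quadrant}")
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for quad in QUADRANTS:
        (vlo, vhi), (alo, ahi) = _QUADRANT_BOXES[quad]
        val = rng.uniform(vlo, vhi, size=n_per_quadrant)
        aro = rng.uniform(alo, ahi, size=n_per_quadrant)
        for v, a in zip(val, aro):
            rows.append((sid, float(v), float(a), quad))
            sid += 1
    table = pd.DataFrame(rows, columns=["stimulus_id", "valence", "arousal", "quadrant"])
    return StimulusSet(table=table)


def generate_schedule(stimuli: StimulusSet, n_sessions: int = 8, seed: int = 0) -> TrialSchedule:
    """Pseudo-random, session-balanced presentation order.

    Each session receives ``n_per_quadrant / n_sessions`` stimuli from every
    quadrant; within a session the order is shuffled.  With the 160-stimulus
    default and 8 sessions this yields 20 trials per session, 5 per quadrant.
    """
    if n_sessions < 1:
        raise ValueError(f"n_sessions must be >= 1, got {n_sessions}")
    counts = stimuli.table["quadrant"].value_counts()
    for quad in QUADRANTS:
        c = int(counts.get(quad, 0))
        if c % n_sessions != 0:
            raise ValueError(
                f"quadrant {quad} has {c} stimuli, not divisible by {n_sessions} sessions"
            )
    rng = np.random.default_rng(seed)
    per_session: list[list[int]] = [[] for _ in range(n_sessions)]
    for quad in QUADRANTS:
        ids = stimuli.table.loc[stimuli.table["quadrant"] == quad, "stimulus_id"].to_numpy()
        ids = rng.permutation(ids)
        for s, chunk in enumerate(np.split(ids, n_sessions)):
            per_session[s].extend(int(i) for i in chunk)
    rows = []
    for s in range(n_sessions):
        order = rng.permutation(len(per_session[s]))
        for t, j in enumerate(order):
            rows.append((s, t, per_session[s][j]))
    table = pd.DataFrame(rows, columns=["session_index", "trial_index", "stimulus_id"])
    return TrialSchedule(table=table)
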