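"""Scoring of the behavioral assessments.

Two instruments are scored here:

* the **dynamic visual cognition (DVC) test**, a button-press detection
  task with signal trials (closed octagon) and noise trials (open
  octagon), summarized by the moving-body recognition (DMD) ratio; and
* the **driving safety performance (DSP) assessment**, instructor
  ratings at six closed-circuit locations (P1..P6), each a sum of
  three-point category scores.

The DMD ratio is implemented in two conventions.  The published formula
divides *positive responses to signals plus false responses to noise*
by the total trial count — a false press on noise raises the score,
which is surprising for a recognition rate.  ``verbatim`` implements
that formula literally and is the default; ``corrected`` counts hits
plus correct rejections instead.  The convention used is stamped into
every scored output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import pandas as pd

TASKS = ("tracking", "sudden")
CONVENTIONS = ("verbatim", "corrected")

#: Rating categories assessed at each course location.
DSP_CATEGORIES: dict[str, tuple[str, ...]] = {
    "P1": ("signalling", "searching", "steering"),
    "P2": ("searching", "speeding", "signalling", "positioning"),
    "P3": ("searching", "speeding"),
    "P4": ("searching", "stability"),
    "P5": ("searching", "speeding"),
    "P6": ("searching", "speeding", "signalling", "positioning"),
}

#: Legal score range per location: (#categories, 3 * #categories).
DSP_LOCATION_RANGES: dict[str, tuple[int, int]] = {
    f"dsp_{loc.lower()}": (len(cats), 3 * len(cats))
    for loc, cats in DSP_CATEGORIES.items()
}


class Trial(NamedTuple):
    task: str       # 'tracking' or 'sudden'
    stimulus: str   # 'signal' (closed octagon) or 'noise' (open octagon)
    pressed: bool


@dataclass
class DvcSession:
    """An ordered sequence of DVC trials, possibly spanning both tasks."""

    trials: list[Trial]

    def __post_init__(self) -> None:
        for t in self.trials:
            if t.task not in TASKS:
                raise ValueError(f"unknown task {t.task!r}")
            if t.stimulus not in ("signal", "noise"):
                raise ValueError(f"unknown stimulus {t.stimulus!r}")

    def counts(self, task: str) -> tuple[int, int, int, int]:
        """(n_signal, n_noise, pressed_on_signal, pressed_on_noise)."""
        sig = [t for t in self.trials if t.task == task and t.stimulus == "signal"]
        noi = [t for t in self.trials if t.task == task and t.stimulus == "noise"]
        return (
            len(sig),
            len(noi),
            sum(t.pressed for t in sig),
            sum(t.pressed for t in noi),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trials, columns=["task", "stimulus", "pressed"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DvcSession":
        missing = {"task", "stimulus", "pressed"} - set(df.columns)
        if missing:
            raise ValueError(f"DVC trial table is missing columns: {sorted(missing)}")
        return cls([
            Trial(str(r.task), str(r.stimulus), bool(r.pressed))
            for r in df.itertuples()
        ])


def dmd_ratio(session: DvcSession, task: str, convention: str = "verbatim") -> float:
    """Moving-body recognition ratio for one task, in [0, 1].

    verbatim:   (pressed on signal + pressed on noise)   / all trials
    corrected:  (pressed on signal + unpressed on noise) / all trials
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    n_sig, n_noi, hit, fa = session.counts(task)
    if n_sig < 1 or n_noi < 1:
        raise ValueError(
            f"task {task!r} needs at least one signal and one noise trial"
        )
    numer = hit + (fa if convention == "verbatim" else n_noi - fa)
    return numer / (n_sig + n_noi)


@dataclass
class DmdScores:
    """DMD ratios for both tasks with the convention they were scored under."""

    tracking: float
    sudden: float
    convention: str

    def scaled(self) -> dict[str, float]:
        """On the 0-100 scale used in cohort tables."""
        return {
            "dvc_tracking": 100.0 * self.tracking,
            "dvc_sudden": 100.0 * self.sudden,
            "convention": self.convention,
        }


def score_dvc(session: DvcSession, convention: str = "verbatim") -> DmdScores:
    return DmdScores(
        tracking=dmd_ratio(session, "tracking", convention),
        sudden=dmd_ratio(session, "sudden", convention),
        convention=convention,
    )


@dataclass
class DspAssessment:
    """Instructor ratings: location -> category -> score in {1, 2, 3}."""

    ratings: dict[str, dict[str, int]]

    def validate(self) -> None:
        if set(self.ratings) != set(DSP_CATEGORIES):
            missing = set(DSP_CATEGORIES) - set(self.ratings)
            extra = set(self.ratings) - set(DSP_CATEGORIES)
            raise ValueError(
                f"assessment locations wrong: missing {sorted(missing)}, "
                f"unexpected {sorted(extra)}"
            )
        for loc, cats in DSP_CATEGORIES.items():
            got = self.ratings[loc]
            if set(got) != set(cats):
                raise ValueError(
                    f"{loc}: expected categories {sorted(cats)}, got {sorted(got)}"
                )
            for cat, score in got.items():
                if not (isinstance(score, (int,)) and 1 <= score <= 3):
                    raise ValueError(
                        f"{loc}/{cat}: score {score!r} not an integer in 1..3"
                    )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (loc, cat, score)
            for loc, cats in self.ratings.items()
            for cat, score in cats.items()
        ]
        return pd.DataFrame(rows, columns=["location", "category", "score"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DspAssessment":
        missing = {"location", "category", "score"} - set(df.columns)
        if missing:
            raise ValueError(f"DSP table is missing columns: {sorted(missing)}")
        ratings: dict[str, dict[str, int]] = {}
        for r in df.itertuples():
            ratings.setdefault(str(r.location), {})[str(r.category)] = int(r.score)
        return cls(ratings)


@dataclass
class DspScores:
    per_location: dict[str, int]
    total: int


def score_dsp(assessment: DspAssessment) -> DspScores:
    """Sum category ratings per location; the total sums the six locations."""
    assessment.validate()
    per_loc = {
        loc: int(sum(assessment.ratings[loc][c] for c in cats))
        for loc, cats in DSP_CATEGORIES.items()
    }
    return DspScores(per_location=per_loc, total=int(sum(per_loc.values())))


def score_many_dsp(frames: Iterable[tuple[str, pd.DataFrame]]) -> pd.DataFrame:
    """Score several participants' rating tables into cohort-style columns."""
    rows = []
    for pid, df in frames:
        s = score_dsp(DspAssessment.from_frame(df))
        row = {"id": pid}
        row.update({f"dsp_{k.lower()}": v for k, v in s.per_location.items()})
        row["dsp_total"] = s.total
        rows.append(row)
    return pd.DataFrame(rows)
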