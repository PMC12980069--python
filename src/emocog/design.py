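"""Fixed layouts of the three touchscreen paradigms.

Each task has a practice phase (block 0, excluded from analysis) and a main
phase with exact, non-stochastic condition counts:

* eFlanker  — 2 blocks x 90 trials; 9 target x distractor emotion cells,
  20 trials each; every trial requires a response (choose the face matching
  the target emotion).
* eGoNoGo   — 2 blocks x 60 trials; stimuli are parachute-color x emotion
  combinations (2 emotions: positive/negative). Two color-emotion
  combinations are targets; target trials are oversampled to 40% of the
  session (48 targets, 72 non-targets).
* eStroop   — 3 blocks x 36 trials; 3 colors x 3 emotions, 12 trials per
  combination; one color is the target (36 go, 72 no-go trials).

Go trials on eGoNoGo/eStroop carry a 2000 ms response deadline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

POSITIVE, NEUTRAL, NEGATIVE = "positive", "neutral", "negative"
EMOTIONS = (POSITIVE, NEUTRAL, NEGATIVE)
GONOGO_EMOTIONS = (POSITIVE, NEGATIVE)
COLORS = ("red", "blue", "yellow")


@dataclass(frozen=True)
class TaskDesign:
    """Static description of one task's trial layout."""

    task: str
    practice_trials: int
    main_blocks: int
    trials_per_block: int
    #: response deadline for go/target trials, ms (None = wait indefinitely)
    response_deadline_ms: float | None
    #: how long a no-go stimulus stays on screen, ms (None for eFlanker)
    nontarget_window_ms: float | None

    @property
    def main_trials(self) -> int:
        return self.main_blocks * self.trials_per_block


TASK_DESIGNS: dict[str, TaskDesign] = {
    "eflanker": TaskDesign("eflanker", 18, 2, 90, None, None),
    "egonogo": TaskDesign("egonogo", 20, 2, 60, 2000.0, 1500.0),
    "estroop": TaskDesign("estroop", 12, 3, 36, 2000.0, 2500.0),
}

TASKS = tuple(TASK_DESIGNS)

_CONDITION_COLUMNS = ["target_emotion", "distractor_emotion", "color", "is_target"]


def base_conditions(task: str, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Canonical (unshuffled) main-phase condition table for ``task``.

    The eGoNoGo target color-emotion pairing and the eStroop target color are
    counterbalanced across participants in the study; pass ``rng`` to draw a
    random assignment, otherwise a fixed default is used.

    Returns a frame with columns target_emotion, distractor_emotion, color,
    is_target whose row counts are the exact design counts.
    """
    absent = float("nan")
    if task == "eflanker":
        rows = [
            (t, d, absent, True)
            for t in EMOTIONS
            for d in EMOTIONS
            for _ in range(20)
        ]
    elif task == "egonogo":
        colors = list(COLORS)
        if rng is not None:
            colors = list(rng.permutation(COLORS))
        # two target combinations, e.g. blue+positive and yellow+negative
        targets = [(POSITIVE, colors[0]), (NEGATIVE, colors[1])]
        combos = [(e, c) for e in GONOGO_EMOTIONS for c in COLORS]
        nontargets = [combo for combo in combos if combo not in targets]
        rows = [(e, absent, c, True) for e, c in targets for _ in range(24)]
        rows += [(e, absent, c, False) for e, c in nontargets for _ in range(18)]
    elif task == "estroop":
        target_color = COLORS[0] if rng is None else str(rng.choice(COLORS))
        rows = [
            (e, absent, c, c == target_color)
            for e in EMOTIONS
            for c in COLORS
            for _ in range(12)
        ]
    else:
        raise ValueError(f"unknown task {task!r}")
    frame = pd.DataFrame(rows, columns=_CONDITION_COLUMNS)
    frame["distractor_emotion"] = frame["distractor_emotion"].astype(object)
    frame["color"] = frame["color"].astype(object)
    return frame


def expected_condition_counts(task: str) -> pd.Series:
    """Main-phase trial count per condition cell, for design conformance checks.

    Cells are (target_emotion, is_target) for the go/no-go style tasks —
    invariant to the counterbalanced color assignment — and
    (target_emotion, distractor_emotion) for the eFlanker.
    """
    base = base_conditions(task)
    if task == "eflanker":
        return base.groupby(["target_emotion", "distractor_emotion"]).size()
    return base.groupby(["target_emotion", "is_target"]).size()
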