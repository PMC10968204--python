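"""Stress-window labeling from per-window self-reports.

Each 15-min experiment window carries a task-difficulty rating (1–10), a
stress rating (1–7) and SAM valence/arousal/dominance scores. The
operational rule labels a window *high* stress when difficulty >= 7 and
stress >= 5, *low* when both ratings are <= 2 or the window is a baseline
period, and *unlabeled* otherwise. A lenient variant (difficulty > 6 and
stress > 4 for high; both < 3 for low) is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

HIGH, LOW, UNLABELED = "high", "low", "unlabeled"


@dataclass(frozen=True)
class SelfReport:
    subject: str
    window: int
    difficulty: int  # 1-10
    stress: int  # 1-7
    sam_valence: int | None = None
    sam_arousal: int | None = None
    sam_dominance: int | None = None
    raw_items: dict = field(default_factory=dict)  # STAI / appraisal / TLX, unscored

    def __post_init__(self) -> None:
        if not 1 <= self.difficulty <= 10:
            raise ValueError("difficulty must be in 1..10")
        if not 1 <= self.stress <= 7:
            raise ValueError("stress must be in 1..7")
        for name in ("sam_valence", "sam_arousal", "sam_dominance"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class WindowLabel:
    window: int
    label: str  # high | low | unlabeled
    is_baseline: bool = False


def label_window(report: SelfReport, is_baseline: bool = False,
                 rule: str = "strict") -> WindowLabel:
    """Label one window from its self-report.

    ``rule="strict"`` (default): high iff difficulty >= 7 and stress >= 5;
    low iff (difficulty <= 2 and stress <= 2) or baseline.
    ``rule="lenient"``: high iff difficulty > 6 and stress > 4; low iff
    (difficulty < 3 and stress < 3) or baseline.
    """
    d, s = report.difficulty, report.stress
    if rule == "strict":
        high = d >= 7 and s >= 5
        low = (d <= 2 and s <= 2) or is_baseline
    elif rule == "lenient":
        high = d > 6 and s > 4
        low = (d < 3 and s < 3) or is_baseline
    else:
        raise ValueError(f"unknown labeling rule {rule!r}")
    if high and not is_baseline:
        label = HIGH
    elif low:
        label = LOW
    else:
        label = UNLABELED
    return WindowLabel(window=report.window, label=label, is_baseline=is_baseline)


def label_reports(reports: pd.DataFrame, rule: str = "strict") -> pd.DataFrame:
    """Vectorized labeling of a self-report table.

    Expects columns ``subject, window, difficulty, stress`` and optionally
    ``valence, arousal, dominance, is_baseline``; returns the table with a
    ``label`` column appended.
    """
    df = reports.copy()
    if "is_baseline" not in df.columns:
        df["is_baseline"] = False
    labels = [
        label_window(
            SelfReport(subject=str(r.subject), window=int(r.window),
                       difficulty=int(r.difficulty), stress=int(r.stress)),
            is_baseline=bool(r.is_baseline), rule=rule,
        ).label
        for r in df.itertuples()
    ]
    df["label"] = labels
    return df
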