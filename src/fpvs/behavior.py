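"""Scoring of the orthogonal fixation-cross color-change task.

A key press is correct if it falls in the [100, 2000) ms window after a
color change; presses are matched greedily to the earliest unmatched change
whose window contains them (the generator's 2-s minimum change gap makes
overlapping windows rare). Accuracy is hits/changes; reaction times are
defined over hits only.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import SequenceEvents

RESPONSE_WINDOW = (0.1, 2.0)  # s after a change, half-open


@dataclass
class DetectionScore:
    n_changes: int
    n_hits: int
    rts: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_false_alarms: int = 0

    def __post_init__(self) -> None:
        if self.n_hits > self.n_changes:
            raise ValueError("more hits than changes")
        self.rts = np.asarray(self.rts, dtype=float)

    @property
    def accuracy(self) -> float | None:
        """Hit proportion; None (missing) when there were no changes."""
        if self.n_changes == 0:
            return None
        return self.n_hits / self.n_changes

    @property
    def mean_rt(self) -> float | None:
        return float(self.rts.mean()) if self.rts.size else None


def score_detection(
    events: SequenceEvents | np.ndarray,
    presses: np.ndarray,
    window: tuple[float, float] = RESPONSE_WINDOW,
) -> DetectionScore:
    """Match presses to color changes and score one sequence.

    Each press is assigned to at most one change — the earliest unmatched
    change whose response window contains it; unmatched presses count as
    false alarms.
    """
    onsets = events.onsets if isinstance(events, SequenceEvents) else np.asarray(events, float)
    presses = np.sort(np.asarray(presses, dtype=float))
    lo, hi = window
    matched = np.zeros(len(onsets), dtype=bool)
    rts = []
    false_alarms = 0
    for p in presses:
        hit = None
        for i, t in enumerate(onsets):
            if matched[i]:
                continue
            if t + lo <= p < t + hi:
                hit = i
                break
            if t + lo > p:
                break
        if hit is None:
            false_alarms += 1
        else:
            matched[hit] = True
            rts.append(p - onsets[hit])
    return DetectionScore(
        n_changes=len(onsets), n_hits=int(matched.sum()),
        rts=np.asarray(rts), n_false_alarms=false_alarms,
    )


def aggregate_scores(scores: list[DetectionScore]) -> DetectionScore:
    """Pool sequences: accuracy over total changes (change-weighted), RT over
    all hits. Missing sequences are simply absent (scored over available)."""
    if not scores:
        raise ValueError("no sequence scores to aggregate")
    return DetectionScore(
        n_changes=sum(s.n_changes for s in scores),
        n_hits=sum(s.n_hits for s in scores),
        rts=np.concatenate([s.rts for s in scores]) if scores else np.empty(0),
        n_false_alarms=sum(s.n_false_alarms for s in scores),
    )


def score_study(
    events: pd.DataFrame, presses: pd.DataFrame, design_sessions: pd.DataFrame
) -> pd.DataFrame:
    """Per-participant, per-treatment detection scores for a whole study.

    ``events``/``presses`` are the long CSV tables (times in s from sequence
    onset); returns one row per participant x session with accuracy, mean
    RT, counts and false alarms.
    """
    rows = []
    for (pid, session), sess in design_sessions.groupby(["participant", "session"]):
        seq_scores = []
        e_ps = events[(events.participant == pid) & (events.session == session)]
        p_ps = presses[(presses.participant == pid) & (presses.session == session)]
        for qi in sorted(e_ps["sequence"].unique()):
            ev = e_ps[e_ps.sequence == qi]["onset_s"].to_numpy()
            pr = p_ps[p_ps.sequence == qi]["time_s"].to_numpy()
            seq_scores.append(score_detection(ev, pr))
        agg = aggregate_scores(seq_scores) if seq_scores else DetectionScore(0, 0)
        rows.append(
            dict(
                participant=pid, session=session,
                treatment=sess["treatment"].iloc[0],
                session_order=sess["session_order"].iloc[0],
                accuracy=agg.accuracy, mean_rt=agg.mean_rt,
                n_changes=agg.n_changes, n_hits=agg.n_hits,
                n_false_alarms=agg.n_false_alarms,
            )
        )
    return pd.DataFrame(rows)
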