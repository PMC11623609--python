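"""Event handling for room/object recall experiments.

Converts timestamped transcripts and stimulus schedules into TR-resolution
event matrices, and computes behavioral recall scores, speaking-time
deviations, and the free-recall contiguity statistic.

A TR (repetition time) is the sampling interval of the neural timeseries,
1.3 s in the design this package emulates. TR ``t`` covers the half-open
interval ``[t*TR, (t+1)*TR)`` (0-based) and receives the label of the
segment containing the TR midpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KIND_NONE",
    "KIND_ROOM",
    "KIND_OBJECT",
    "TranscriptSegment",
    "EventMatrix",
    "RecallScore",
    "events_from_segments",
    "video_events",
    "score_recall",
    "speaking_time_test",
    "contiguity_analysis",
    "segments_to_frame",
    "segments_from_frame",
]

NO_LABEL = -1

KIND_NONE = "none"
KIND_ROOM = "room"
KIND_OBJECT = "object"


@dataclass(frozen=True)
class TranscriptSegment:
    """One timestamped verbal description (a room or an object)."""

    label: int
    kind: str  # "room" | "object"
    onset: float  # seconds
    offset: float  # seconds

    def __post_init__(self) -> None:
        if self.kind not in (KIND_ROOM, KIND_OBJECT):
            raise ValueError(f"kind must be 'room' or 'object', got {self.kind!r}")
        if not self.offset > self.onset:
            raise ValueError(
                f"segment offset ({self.offset}) must exceed onset ({self.onset})"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class EventMatrix:
    """Per-TR condition labels and kinds.

    ``labels[t]`` is the condition id active at TR ``t`` (or -1 for none);
    ``kinds[t]`` is "room", "object" or "none".
    """

    labels: np.ndarray
    kinds: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.kinds = np.asarray(self.kinds, dtype=object)
        if self.labels.shape != self.kinds.shape:
            raise ValueError("labels and kinds must have the same length")

    @property
    def n_tr(self) -> int:
        return len(self.labels)

    def labeled(self, kind: Optional[str] = None) -> np.ndarray:
        """Boolean mask of TRs carrying a label (optionally of one kind)."""
        mask = self.labels != NO_LABEL
        if kind is not None:
            mask &= self.kinds == kind
        return mask


@dataclass(frozen=True)
class RecallScore:
    participant_id: str
    task: str  # "guided" | "free"
    run: int
    n_correct: int
    n_total: int

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total


def _check_same_kind_overlaps(segments: Sequence[TranscriptSegment]) -> None:
    for kind in (KIND_ROOM, KIND_OBJECT):
        sub = sorted(
            (s for s in segments if s.kind == kind), key=lambda s: (s.onset, s.offset)
        )
        offenders = [
            (a, b)
            for a, b in zip(sub, sub[1:])
            if b.onset < a.offset  # touching at a boundary is fine
        ]
        if offenders:
            desc = "; ".join(
                f"{a.kind} {a.label} [{a.onset:.2f},{a.offset:.2f}) overlaps "
                f"{b.kind} {b.label} [{b.onset:.2f},{b.offset:.2f})"
                for a, b in offenders
            )
            raise ValueError(f"overlapping same-kind segments: {desc}")


def events_from_segments(
    segments: Sequence[TranscriptSegment],
    tr_seconds: float,
    n_tr: int,
) -> EventMatrix:
    """Downsample timestamped segments to a TR-resolution event matrix.

    TR ``t`` receives the label of the segment containing the TR midpoint
    ``(t + 0.5) * tr_seconds``; TRs whose midpoint no segment covers stay
    unlabeled. Same-kind segments must not overlap. If a room and an object
    segment both cover a midpoint (possible only in malformed transcripts;
    real transcripts serialize them) the later-onset segment wins.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    _check_same_kind_overlaps(segments)
    total = n_tr * tr_seconds
    for s in segments:
        if s.offset > total + 1e-9:
            raise ValueError(
                f"segment offset {s.offset} exceeds run duration {total:.3f} s"
            )
    labels = np.full(n_tr, NO_LABEL, dtype=int)
    kinds = np.full(n_tr, KIND_NONE, dtype=object)
    mid = (np.arange(n_tr) + 0.5) * tr_seconds
    for seg in sorted(segments, key=lambda s: s.onset):
        hit = (mid >= seg.onset) & (mid < seg.offset)
        labels[hit] = seg.label
        kinds[hit] = seg.kind
    return EventMatrix(labels=labels, kinds=kinds, tr_seconds=tr_seconds)


def video_events(
    order: Sequence[int],
    video_seconds: float,
    isi_seconds: float,
    tr_seconds: float,
    kind: str = KIND_ROOM,
    n_tr: Optional[int] = None,
    pad_seconds: float = 0.0,
) -> EventMatrix:
    """Block-design schedule: each condition's video, then an inter-stimulus gap.

    Condition ``order[i]`` occupies ``[i*(video+isi), i*(video+isi)+video)``.
    The same midpoint rule as :func:`events_from_segments` applies.
    """
    if video_seconds <= 0 or isi_seconds < 0:
        raise ValueError("durations must be positive (isi may be zero)")
    segs = [
        TranscriptSegment(
            label=int(c),
            kind=kind,
            onset=i * (video_seconds + isi_seconds),
            offset=i * (video_seconds + isi_seconds) + video_seconds,
        )
        for i, c in enumerate(order)
    ]
    if n_tr is None:
        total = len(order) * (video_seconds + isi_seconds) + pad_seconds
        n_tr = int(np.ceil(total / tr_seconds))
    return events_from_segments(segs, tr_seconds, n_tr)


def video_segments(
    order: Sequence[int],
    video_seconds: float,
    isi_seconds: float,
    kind: str = KIND_ROOM,
) -> list[TranscriptSegment]:
    """Second-resolution segments for a block-design video run."""
    return [
        TranscriptSegment(
            label=int(c),
            kind=kind,
            onset=i * (video_seconds + isi_seconds),
            offset=i * (video_seconds + isi_seconds) + video_seconds,
        )
        for i, c in enumerate(order)
    ]


def score_recall(
    segments: Sequence[TranscriptSegment],
    task: str,
    pairing,
    cued_path: Optional[Sequence[int]] = None,
    run: int = 0,
    participant_id: str = "",
) -> RecallScore:
    """Score a recall transcript by which paired objects were ever mentioned.

    Guided recall: an object counts as correctly recalled if it is paired
    (via ``pairing``) to one of the 5 cued rooms and its label appears
    anywhere in the transcript, regardless of order or room association.
    Free recall: same criterion over all rooms' objects.
    """
    room_to_object = np.asarray(pairing.room_to_object)
    if task == "guided":
        if cued_path is None:
            raise ValueError("guided recall requires a cued_path of rooms")
        target_objects = {int(room_to_object[r]) for r in cued_path}
    elif task == "free":
        target_objects = {int(o) for o in room_to_object}
    else:
        raise ValueError(f"task must be 'guided' or 'free', got {task!r}")
    recalled = {s.label for s in segments if s.kind == KIND_OBJECT}
    n_correct = len(target_objects & recalled)
    return RecallScore(
        participant_id=participant_id,
        task=task,
        run=run,
        n_correct=n_correct,
        n_total=len(target_objects),
    )


def speaking_time_test(
    transcripts: Sequence[Sequence[TranscriptSegment]],
    kind: str,
    n_conditions: int,
) -> pd.DataFrame:
    """Test which conditions were spoken about for atypically long (or short).

    For each participant the total speaking time per condition is computed
    (conditions never spoken get 0 s, they are not dropped), and each
    condition's time is expressed as a deviation from that participant's
    grand mean across conditions. Per condition, a one-sample t-test of the
    deviations against zero is Bonferroni-corrected over ``n_conditions``.
    Conditions with zero variance across participants get NaN t and p.
    """
    n_participants = len(transcripts)
    if n_participants < 3:
        raise ValueError("speaking_time_test requires at least 3 participants")
    times = np.zeros((n_participants, n_conditions))
    for i, segs in enumerate(transcripts):
        for s in segs:
            if s.kind == kind:
                if not 0 <= s.label < n_conditions:
                    raise ValueError(f"segment label {s.label} out of range")
                times[i, s.label] += s.duration
    deviations = times - times.mean(axis=1, keepdims=True)
    t = np.full(n_conditions, np.nan)
    p = np.full(n_conditions, np.nan)
    for c in range(n_conditions):
        d = deviations[:, c]
        if np.ptp(d) == 0.0:
            continue  # zero variance: t undefined, flagged as NaN
        t[c], p[c] = stats.ttest_1samp(d, 0.0)
    p_bonf = np.minimum(p * n_conditions, 1.0)
    return pd.DataFrame(
        {
            "condition": np.arange(n_conditions),
            "mean_seconds": times.mean(axis=0),
            "t": t,
            "p": p,
            "p_bonferroni": p_bonf,
        }
    )


def contiguity_analysis(
    room_sequences: Sequence[Sequence[int]],
    graph,
) -> dict:
    """Do recall transitions land on spatially adjacent rooms above chance?

    Consecutive repeats are collapsed first (self-transitions excluded). Per
    participant, ``observed`` is the fraction of transitions that land on a
    room adjacent to the current room; ``chance`` is the mean over
    transitions of degree(current) / (n_rooms - 1). A paired t-test compares
    observed vs chance across participants. Participants with fewer than two
    distinct-in-a-row recalls are excluded with a warning.
    """
    adjacency = np.asarray(getattr(graph, "adjacency", graph), dtype=bool)
    n_rooms = adjacency.shape[0]
    degrees = adjacency.sum(axis=1)
    observed, chance, kept = [], [], []
    for idx, seq in enumerate(room_sequences):
        dedup = [r for i, r in enumerate(seq) if i == 0 or r != seq[i - 1]]
        if len(dedup) < 2:
            warnings.warn(
                f"participant {idx}: fewer than 2 distinct recalls, excluded"
            )
            continue
        cur = np.asarray(dedup[:-1])
        nxt = np.asarray(dedup[1:])
        obs = adjacency[cur, nxt].mean()
        cha = (degrees[cur] / (n_rooms - 1)).mean()
        observed.append(obs)
        chance.append(cha)
        kept.append(idx)
    observed = np.asarray(observed)
    chance = np.asarray(chance)
    if len(observed) >= 2 and np.ptp(observed - chance) > 0:
        t, p = stats.ttest_rel(observed, chance)
    else:
        t, p = np.nan, np.nan
    return {
        "participants": np.asarray(kept),
        "observed": observed,
        "chance": chance,
        "t": float(t),
        "p": float(p),
    }


def segments_to_frame(segments: Iterable[TranscriptSegment]) -> pd.DataFrame:
    """Serialize segments as a BIDS-events-style table."""
    rows = [
        {
            "onset": s.onset,
            "duration": s.duration,
            "trial_type": s.label,
            "event_kind": s.kind,
        }
        for s in sorted(segments, key=lambda s: s.onset)
    ]
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "event_kind"])


def segments_from_frame(frame: pd.DataFrame) -> list[TranscriptSegment]:
    return [
        TranscriptSegment(
            label=int(r.trial_type),
            kind=str(r.event_kind),
            onset=float(r.onset),
            offset=float(r.onset) + float(r.duration),
        )
        for r in frame.itertuples()
    ]
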