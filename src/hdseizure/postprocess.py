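"""Trailing-window vote over per-segment predictions and seizure
detection with latency.

Per-segment ictal/inter-ictal labels are summed over the trailing 5 s
(k = round(vote_window_s / window_s) segments, fewer at the start of the
recording), sliding one segment at a time.  An alarm fires wherever the
count strictly exceeds the patient-dependent threshold t_p.  The
detection time of a seizure is the end time of the first alarmed segment
at or after the annotated onset; latency = detection − onset (≥ 0 by
construction).  Alarms strictly before the onset segment are recorded as
false alarms, never as detections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_model import SeizureAnnotation


@dataclass(frozen=True)
class VotingConfig:
    """Trailing-vote parameters.

    t_p defaults to half the number of segments in the vote window
    (5 at 0.5 s segments, 10 at 0.25 s); it is patient-dependent in
    deployment and freely overridable.
    """

    window_s: float
    vote_window_s: float = 5.0
    t_p: int | None = None

    def __post_init__(self) -> None:
        if self.vote_window_s < self.window_s:
            raise ValueError("vote window must cover at least one segment")
        if self.t_p is not None and not 0 <= self.t_p <= self.k:
            raise ValueError(f"t_p must lie in [0, {self.k}]")

    @property
    def k(self) -> int:
        """Segments per vote window."""
        return int(round(self.vote_window_s / self.window_s))

    @property
    def threshold(self) -> int:
        return self.t_p if self.t_p is not None else self.k // 2


@dataclass
class DetectionOutcome:
    """Voted detection result for one recording (≤ 1 ictal annotation)."""

    votes: np.ndarray
    alarm_times_s: np.ndarray  # end times of alarmed segments
    detection_time_s: float | None
    latency_s: float | None
    n_false_alarms: int = 0

    @property
    def detected(self) -> bool:
        return self.latency_s is not None


def vote(labels, config: VotingConfig) -> np.ndarray:
    """Trailing sum of the last k segment labels at every segment.

    The sum is over however many segments exist, up to k — shorter at the
    start of the recording.
    """
    labels = np.asarray(labels, dtype=np.int64).ravel()
    if labels.size == 0:
        raise ValueError("empty label sequence")
    k = config.k
    csum = np.concatenate([[0], np.cumsum(labels)])
    idx = np.arange(1, labels.size + 1)
    lo = np.maximum(idx - k, 0)
    return csum[idx] - csum[lo]


def detect(
    votes,
    annotations: list[SeizureAnnotation],
    config: VotingConfig,
) -> DetectionOutcome:
    """Turn a vote sequence into alarms, one detection, and its latency.

    Segment i spans [i·window_s, (i+1)·window_s); candidates for the
    detection are segments from the one containing the onset onwards, so
    a detector alarming throughout reports latency ≤ window_s.
    """
    votes = np.asarray(votes, dtype=np.int64).ravel()
    t_p = config.threshold
    w = config.window_s
    alarmed = votes > t_p
    end_times = (np.arange(votes.size) + 1) * w

    ictal = [a for a in annotations if a.kind == "ictal"]
    if len(ictal) > 1:
        raise ValueError("detect expects at most one ictal annotation")
    if not ictal:
        return DetectionOutcome(
            votes=votes,
            alarm_times_s=end_times[alarmed],
            detection_time_s=None,
            latency_s=None,
            n_false_alarms=int(alarmed.sum()),
        )

    onset = ictal[0].onset_s
    onset_seg = int(np.floor(onset / w))
    candidates = np.flatnonzero(alarmed[onset_seg:]) + onset_seg
    if candidates.size:
        det_t = float(end_times[candidates[0]])
        latency = max(0.0, det_t - onset)
    else:
        det_t = None
        latency = None
    n_false = int(alarmed[:onset_seg].sum())
    return DetectionOutcome(
        votes=votes,
        alarm_times_s=end_times[alarmed],
        detection_time_s=det_t,
        latency_s=latency,
        n_false_alarms=n_false,
    )
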