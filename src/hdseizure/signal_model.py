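"""Data model and I/O for annotated multichannel iEEG recordings.

A :class:`Recording` holds an ``M × T`` voltage matrix (``M`` electrodes,
``T`` samples), its sampling rate, and neurologist-style seizure
annotations in seconds.  Analysis operates on a :class:`WindowGrid` of
contiguous, non-overlapping fixed-length windows aligned to the LBP code
stream (which is 6 samples shorter than the raw signal); a trailing
partial window is dropped rather than padded.

All timestamps are seconds from recording start; annotation intervals
are half-open ``[onset, offset)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Number of raw samples consumed by one LBP code.
LBP_POINTS = 7


@dataclass(frozen=True)
class SeizureAnnotation:
    """A single annotated ictal interval, half-open ``[onset_s, offset_s)``."""

    onset_s: float
    offset_s: float
    kind: str = "ictal"

    def __post_init__(self) -> None:
        if not 0 <= self.onset_s < self.offset_s:
            raise ValueError(
                f"invalid annotation interval [{self.onset_s}, {self.offset_s})"
            )

    def contains(self, t: float) -> bool:
        return self.onset_s <= t < self.offset_s


@dataclass
class Recording:
    """Multichannel recording: ``data`` is M channels × T samples."""

    data: np.ndarray
    fs: float = 512.0
    channel_ids: list[str] | None = None
    annotations: list[SeizureAnnotation] = field(default_factory=list)
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels × samples matrix")
        m, t = self.data.shape
        if m < 1:
            raise ValueError("recording needs at least one channel")
        if t < LBP_POINTS:
            raise ValueError(
                f"recording too short for LBP: {t} samples < {LBP_POINTS}"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i}" for i in range(m)]
        if len(self.channel_ids) != m:
            raise ValueError("channel_ids length must equal channel count")
        self.annotations = sorted(self.annotations, key=lambda a: a.onset_s)
        prev_end = 0.0
        for a in self.annotations:
            if a.offset_s > self.duration_s + 1e-9:
                raise ValueError(
                    f"annotation [{a.onset_s}, {a.offset_s}) exceeds recording "
                    f"duration {self.duration_s:.3f} s"
                )
            if a.onset_s < prev_end:
                raise ValueError("annotations overlap")
            prev_end = a.offset_s

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass(frozen=True)
class WindowGrid:
    """Contiguous non-overlapping analysis windows over the LBP code stream.

    ``codes_per_window = round(window_s * fs)`` codes per window; the code
    stream has ``T - 6`` entries, so ``n_windows = (T - 6) // codes_per_window``
    and any trailing partial window is dropped.  Window ``w`` covers codes
    ``[w*cpw, (w+1)*cpw)`` and is stamped with the start time of its first
    code (the 6-sample LBP look-back, under 12 ms at 512 Hz, is ignored).
    """

    window_s: float
    codes_per_window: int
    n_windows: int
    start_times_s: np.ndarray
    fs: float

    @classmethod
    def from_recording(cls, recording: Recording, window_s: float) -> "WindowGrid":
        cpw = int(round(window_s * recording.fs))
        if cpw < 1:
            raise ValueError("window shorter than one sample")
        n_codes = recording.n_samples - (LBP_POINTS - 1)
        n_windows = n_codes // cpw
        starts = np.arange(n_windows) * cpw / recording.fs
        return cls(
            window_s=float(window_s),
            codes_per_window=cpw,
            n_windows=n_windows,
            start_times_s=starts,
            fs=recording.fs,
        )

    def center_times_s(self) -> np.ndarray:
        return self.start_times_s + self.window_s / 2.0

    def end_times_s(self) -> np.ndarray:
        return self.start_times_s + self.window_s


def window_labels(recording: Recording, grid: WindowGrid) -> np.ndarray:
    """Per-window class labels: 1 (ictal) iff the window center lies inside
    an ictal annotation, else 0 (inter-ictal).

    Center membership (rather than any-overlap) avoids double-labelling
    windows straddling an onset; the half-open annotation intervals resolve
    an exact boundary tie in favour of the later interval.
    """
    centers = grid.center_times_s()
    labels = np.zeros(grid.n_windows, dtype=np.int8)
    for a in recording.annotations:
        if a.kind != "ictal":
            continue
        labels[(centers >= a.onset_s) & (centers < a.offset_s)] = 1
    return labels


def window_phases(recording: Recording, grid: WindowGrid) -> np.ndarray:
    """Per-window phase codes: 0 pre-ictal, 1 ictal, 2 post-ictal.

    A window is post-ictal when its center falls at or after the offset of
    the last ictal annotation.  Used by the evaluation layer, where
    post-ictal windows are excluded from the inter-ictal class by default.
    """
    labels = window_labels(recording, grid)
    phases = np.where(labels == 1, 1, 0).astype(np.int8)
    ictal = [a for a in recording.annotations if a.kind == "ictal"]
    if ictal:
        last_offset = max(a.offset_s for a in ictal)
        centers = grid.center_times_s()
        phases[(labels == 0) & (centers >= last_offset)] = 2
    return phases


def read_annotations(path: str | Path) -> list[SeizureAnnotation]:
    """Read a sidecar annotation file: JSON ``[{"onset_s":..,"offset_s":..}]``
    or a two-column (onset, offset) CSV with optional header."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        entries = json.loads(path.read_text())
        return [
            SeizureAnnotation(float(e["onset_s"]), float(e["offset_s"]))
            for e in entries
        ]
    df = pd.read_csv(path, header=None)
    if df.shape[1] < 2:
        raise ValueError("annotation CSV needs two columns: onset_s, offset_s")
    # tolerate a header row of names
    first = df.iloc[0]
    if not all(_is_number(v) for v in first[:2]):
        df = df.iloc[1:]
    return [
        SeizureAnnotation(float(r.iloc[0]), float(r.iloc[1]))
        for _, r in df.iterrows()
    ]


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def load_recording(
    path: str | Path,
    annotation_path: str | Path | None = None,
    fs_override: float | None = None,
    patient_id: str | None = None,
) -> Recording:
    """Load a recording from an EDF file or a delimited numeric matrix.

    Delimited matrices may store channels as columns (with a one-line
    header of channel ids) or as rows (no header); orientation is
    auto-detected — a header row means columns are channels, otherwise the
    longer axis is taken as time.  EDF supplies channel names and the
    sampling rate from its own header (requires ``mne``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    annotations: list[SeizureAnnotation] = []
    if annotation_path is not None:
        annotations = read_annotations(annotation_path)

    if path.suffix.lower() == ".edf":
        data, fs, channel_ids = _read_edf(path)
    else:
        data, fs, channel_ids = _read_delimited(path)

    if fs_override is not None:
        fs = float(fs_override)
    if fs is None:
        raise ValueError(
            "sampling rate not present in file; pass fs_override"
        )
    return Recording(
        data=data,
        fs=fs,
        channel_ids=channel_ids,
        annotations=annotations,
        patient_id=patient_id or path.stem,
    )


def _read_edf(path: Path):
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data(), float(raw.info["sfreq"]), list(raw.ch_names)


def _read_delimited(path: Path):
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    with open(path) as fh:
        first_line = fh.readline()
    tokens = [t.strip() for t in first_line.strip().split(sep)]
    has_header = not all(_is_number(t) for t in tokens if t != "")
    try:
        df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
        values = df.to_numpy(dtype=np.float64)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric cells in {path}") from exc
    if has_header:
        # header names the channels -> columns are channels
        data = values.T
        channel_ids = [str(c) for c in df.columns]
    else:
        # orientation heuristic: samples outnumber channels
        data = values.T if values.shape[0] >= values.shape[1] else values
        channel_ids = None
    return data, None, channel_ids


def save_recording_csv(
    recording: Recording,
    path: str | Path,
    annotation_path: str | Path | None = None,
    fmt: str = "%.6g",
) -> None:
    """Write channels-as-columns CSV (header = channel ids) plus an optional
    JSON annotation sidecar, in the same layout :func:`load_recording` reads."""
    path = Path(path)
    header = ",".join(recording.channel_ids)
    np.savetxt(path, recording.data.T, delimiter=",", header=header,
               comments="", fmt=fmt)
    if annotation_path is not None:
        entries = [
            {"onset_s": a.onset_s, "offset_s": a.offset_s}
            for a in recording.annotations
        ]
        Path(annotation_path).write_text(json.dumps(entries, indent=1))
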