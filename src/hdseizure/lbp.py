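"""Local-binary-pattern (LBP) coding of iEEG sample streams.

Each 7-sample segment yields 6 pairwise comparisons of consecutive
samples: bit i is 1 when the later sample is strictly greater than the
earlier one (ties give 0).  The 6 bits are packed MSB-first (earliest
comparison most significant) into an integer code in [0, 63].  Codes are
emitted with stride 1, so a channel of T samples yields T − 6 codes and
code j covers samples [j, j + 6].

Because only order relations between consecutive samples enter the code,
the encoding is invariant to additive offsets and positive rescaling of
the signal — no amplitude normalisation is needed upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_model import LBP_POINTS, Recording

#: Comparisons per code = bits per code.
LBP_BITS = LBP_POINTS - 1

#: Number of distinct codes.
N_CODES = 1 << LBP_BITS

# MSB-first bit weights: earliest comparison is the most significant bit.
_WEIGHTS = (1 << np.arange(LBP_BITS - 1, -1, -1)).astype(np.int64)


@dataclass(frozen=True)
class LbpStream:
    """Per-channel LBP code sequences: ``codes`` is M × (T − 6), values in [0, 63]."""

    codes: np.ndarray
    fs: float

    @property
    def n_channels(self) -> int:
        return self.codes.shape[0]

    @property
    def n_codes(self) -> int:
        return self.codes.shape[1]


def encode_channel(samples) -> np.ndarray:
    """Encode one channel's sample stream into LBP codes.

    Returns a length T − 6 uint8 array; raises for streams shorter than
    7 samples.
    """
    s = np.asarray(samples, dtype=np.float64)
    if s.ndim != 1:
        raise ValueError("encode_channel expects a 1-D sample sequence")
    if s.size < LBP_POINTS:
        raise ValueError(
            f"too short for LBP: {s.size} samples < {LBP_POINTS}"
        )
    bits = (s[1:] > s[:-1]).astype(np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(bits, LBP_BITS)
    return (windows @ _WEIGHTS).astype(np.uint8)


def encode_recording(recording: Recording) -> LbpStream:
    """Encode every channel of a recording; rows stay aligned with channels."""
    bits = (recording.data[:, 1:] > recording.data[:, :-1]).astype(np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(bits, LBP_BITS, axis=1)
    codes = (windows @ _WEIGHTS).astype(np.uint8)
    return LbpStream(codes=codes, fs=recording.fs)


def code_from_bits(bits) -> int:
    """Pack 6 comparison bits (earliest first) into the integer code."""
    bits = np.asarray(bits, dtype=np.int64)
    if bits.shape != (LBP_BITS,) or not np.isin(bits, (0, 1)).all():
        raise ValueError(f"expected {LBP_BITS} binary values")
    return int(bits @ _WEIGHTS)


def enumerate_code_space() -> dict[tuple[int, ...], int]:
    """Map every possible comparison-bit pattern to its code.

    Realizes each of the 2^6 patterns as a concrete 7-sample sequence,
    encodes it, and returns {pattern: code}.  The encoder is a bijection
    onto [0, 63] exactly when the returned codes are all distinct.
    """
    mapping: dict[tuple[int, ...], int] = {}
    for value in range(N_CODES):
        pattern = tuple((value >> (LBP_BITS - 1 - i)) & 1 for i in range(LBP_BITS))
        samples = np.zeros(LBP_POINTS)
        for i, b in enumerate(pattern):
            # strictly increase for a 1-bit, strictly decrease for a 0-bit
            samples[i + 1] = samples[i] + (1.0 if b else -1.0)
        code = int(encode_channel(samples)[0])
        mapping[pattern] = code
    return mapping
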