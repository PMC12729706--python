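"""Binary hyperdimensional encoding of LBP code streams.

Item memory
    Two banks of D-dimensional binary hypervectors: 64 rows for the LBP
    codes and M rows for a patient's electrodes.  Both are drawn from a
    seeded standard-normal generator and binarized by sign (> 0 → 1), so
    each bit is i.i.d. Bernoulli(0.5) and distinct rows sit at a
    normalized Hamming distance concentrated around 0.5
    (quasi-orthogonality).

Encoding
    At each time step the code hypervector of every electrode is bound to
    that electrode's identity hypervector by bit-wise XOR; the M bound
    vectors are bundled by element-wise summation and a strict majority
    threshold (> M/2).  The per-time-step vectors of one analysis window
    (round(window_s · fs) steps) are bundled again the same way (> n/2),
    yielding a single binary hypervector per window.  Exact ties, possible
    for even M or n, resolve to 0 ("exceeds the threshold" is strict).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .lbp import N_CODES, LbpStream
from .signal_model import Recording, WindowGrid

#: Bound vectors gathered per chunk in the windowed encoder (memory cap).
_CHUNK_ELEMS = 1 << 25


@dataclass(frozen=True)
class ItemMemory:
    """Seeded banks of binary hypervectors for LBP codes and electrodes."""

    D: int
    code_hv: np.ndarray  # 64 × D, uint8 in {0,1}
    electrode_hv: np.ndarray  # M × D, uint8 in {0,1}
    seed: int

    @property
    def n_electrodes(self) -> int:
        return self.electrode_hv.shape[0]


@dataclass(frozen=True)
class WindowHV:
    """One analysis window's binary hypervector."""

    bits: np.ndarray
    window_index: int
    start_s: float


def build_item_memory(D: int, M: int, seed: int) -> ItemMemory:
    """Draw the (64 + M) × D Gaussian mapping matrices from a seeded
    generator and binarize by sign.

    The same (D, M, seed) always reproduces a bit-identical memory.  Code
    rows come first in the draw so the code bank does not depend on M.
    """
    if D < 1:
        raise ValueError("hypervector dimension D must be >= 1")
    if M < 1:
        raise ValueError("electrode count M must be >= 1")
    rng = np.random.default_rng(seed)
    gaussian = rng.standard_normal((N_CODES + M, D))
    bits = (gaussian > 0).astype(np.uint8)
    return ItemMemory(
        D=D, code_hv=bits[:N_CODES], electrode_hv=bits[N_CODES:], seed=int(seed)
    )


def gaussian_cosine_sd(D: int, n_pairs: int, seed: int, ddof: int = 1) -> float:
    """Sample standard deviation of the cosine similarity between
    independent pairs of D-dimensional standard-normal vectors.

    Quantifies the quasi-orthogonality of freshly drawn item-memory rows
    before binarization; concentrates around 1/sqrt(D) (≈ 0.03 at D=1000).
    """
    rng = np.random.default_rng(seed)
    u = rng.standard_normal((n_pairs, D))
    v = rng.standard_normal((n_pairs, D))
    cos = np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    return float(np.std(cos, ddof=ddof))


def bind_timestep(codes_at_t, im: ItemMemory) -> np.ndarray:
    """Encode one time step: XOR-bind each electrode's code hypervector to
    its electrode hypervector, bundle across electrodes by summation and a
    strict majority threshold (> M/2)."""
    codes = np.asarray(codes_at_t)
    if codes.min() < 0 or codes.max() >= N_CODES:
        raise ValueError(f"LBP codes must lie in [0, {N_CODES - 1}]")
    m = codes.shape[0]
    if m > im.n_electrodes:
        raise ValueError("more electrodes than item-memory rows")
    bound = im.code_hv[codes] ^ im.electrode_hv[:m]
    s = bound.sum(axis=0)
    return (s * 2 > m).astype(np.uint8)


def _bound_bank(lbp: LbpStream, im: ItemMemory) -> np.ndarray:
    # Pre-XOR each electrode's full code bank: M × 64 × D.
    m = lbp.n_channels
    if m > im.n_electrodes:
        raise ValueError("more electrodes than item-memory rows")
    return im.code_hv[None, :, :] ^ im.electrode_hv[:m, None, :]


def _encode_code_block(codes_block: np.ndarray, bank: np.ndarray) -> np.ndarray:
    """Per-time-step majority vectors for a block of code columns.

    codes_block: M × n; returns n × D uint8.
    """
    m, n = codes_block.shape
    d = bank.shape[2]
    chunk = max(1, _CHUNK_ELEMS // (m * d))
    rows = np.arange(m)[:, None]
    out = np.empty((n, d), dtype=np.uint8)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        gathered = bank[rows, codes_block[:, lo:hi]]  # m × (hi-lo) × D
        s = gathered.sum(axis=0, dtype=np.int32)
        out[lo:hi] = s * 2 > m
    return out


def encode_window(
    lbp: LbpStream, im: ItemMemory, grid: WindowGrid, w_index: int
) -> WindowHV:
    """Encode one complete analysis window into a binary hypervector."""
    if not 0 <= w_index < grid.n_windows:
        raise IndexError(f"window {w_index} outside grid of {grid.n_windows}")
    cpw = grid.codes_per_window
    lo = w_index * cpw
    if lo + cpw > lbp.n_codes:
        raise ValueError("incomplete window: code stream too short")
    bank = _bound_bank(lbp, im)
    step_hvs = _encode_code_block(lbp.codes[:, lo : lo + cpw], bank)
    bits = (step_hvs.sum(axis=0, dtype=np.int64) * 2 > cpw).astype(np.uint8)
    return WindowHV(bits=bits, window_index=w_index,
                    start_s=float(grid.start_times_s[w_index]))


def encode_stream_hv(
    lbp: LbpStream, im: ItemMemory, grid: WindowGrid
) -> np.ndarray:
    """Encode every complete window of a code stream at once.

    Returns an ``n_windows × D`` binary matrix; row w equals
    ``encode_window(..., w).bits``.
    """
    cpw = grid.codes_per_window
    n_win = grid.n_windows
    bank = _bound_bank(lbp, im)
    out = np.empty((n_win, im.D), dtype=np.uint8)
    for w in range(n_win):
        block = lbp.codes[:, w * cpw : (w + 1) * cpw]
        step_hvs = _encode_code_block(block, bank)
        out[w] = step_hvs.sum(axis=0, dtype=np.int64) * 2 > cpw
    return out


def encode_recording_hv(
    recording: Recording, im: ItemMemory, window_s: float
) -> tuple[list[WindowHV], WindowGrid]:
    """LBP-encode a recording and bundle it into per-window hypervectors."""
    from .lbp import encode_recording

    lbp = encode_recording(recording)
    grid = WindowGrid.from_recording(recording, window_s)
    mat = encode_stream_hv(lbp, im, grid)
    hvs = [
        WindowHV(bits=mat[w], window_index=w, start_s=float(grid.start_times_s[w]))
        for w in range(grid.n_windows)
    ]
    return hvs, grid


def hamming(a, b) -> int:
    """Hamming distance between two binary vectors."""
    return int(np.count_nonzero(np.asarray(a) != np.asarray(b)))


def save_item_memory(im: ItemMemory, path: str | Path) -> None:
    """Serialize as JSON: seed/D/M plus hex-packed bit matrices for a
    bit-exact round-trip that does not rely on the generator."""
    payload = {
        "D": im.D,
        "M": im.n_electrodes,
        "seed": im.seed,
        "binarization": "gaussian > 0 -> 1",
        "code_hv_hex": _pack_hex(im.code_hv),
        "electrode_hv_hex": _pack_hex(im.electrode_hv),
    }
    Path(path).write_text(json.dumps(payload))


def load_item_memory(path: str | Path) -> ItemMemory:
    payload = json.loads(Path(path).read_text())
    d, m = payload["D"], payload["M"]
    return ItemMemory(
        D=d,
        code_hv=_unpack_hex(payload["code_hv_hex"], N_CODES, d),
        electrode_hv=_unpack_hex(payload["electrode_hv_hex"], m, d),
        seed=payload["seed"],
    )


def _pack_hex(bits: np.ndarray) -> str:
    return np.packbits(bits, axis=None).tobytes().hex()


def _unpack_hex(hexstr: str, rows: int, d: int) -> np.ndarray:
    raw = np.frombuffer(bytes.fromhex(hexstr), dtype=np.uint8)
    flat = np.unpackbits(raw)[: rows * d]
    return flat.reshape(rows, d).astype(np.uint8)
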