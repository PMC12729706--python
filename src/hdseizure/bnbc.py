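"""Bernoulli naive Bayes over binary window hypervectors, with an
integer lookup-table (LUT) inference path.

Training estimates class priors and per-dimension Bernoulli success
probabilities p_{k,c} by plain counting (no smoothing; zeros are guarded
at inference time).  Exact inference maximises

    log P(y=c) + sum_k [ x_k log p_{k,c} + (1 - x_k) log(1 - p_{k,c}) ].

The LUT path replaces every logarithm with a precomputed integer cost:
probabilities are discretized into 100 bins of width 0.01, and each bin
maps to round(-128 · ln(bin lower edge + 0.001)), clamped to 1 above
0.99.  Classification then minimises an integer cost sum — additions and
table lookups only, no floating point — with identical decisions to the
float path outside near-tie margins.  The scale 128 = 2^7 keeps costs
within 10 bits (max 884) so a D-dimensional total fits easily in 32 bits.

Cost-table convention: the reference cost table for this transform is
matched entry-for-entry by the natural log of the *bin lower edge* plus
offset 0.001, scaled by −128 and rounded half away from zero.  (A
midpoint-plus-0.005 reading of the same transform does not reproduce
those entries; the lower-edge convention is normative here and the
constants are module-level so the choice is visible.)
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

#: LUT scale factor: log-costs are multiplied by -128 = -2^7.
LUT_SCALE = 128
#: Probability bin width; 100 bins cover [0, 1].
LUT_BIN_WIDTH = 0.01
N_LUT_BINS = 100
#: Offset added inside the log to guard p = 0.
LUT_LOG_OFFSET = 0.001
#: Probabilities above this clamp to the minimal cost 1.
LUT_CLAMP = 0.99


@dataclass(frozen=True)
class BnbcModel:
    """Fitted Bernoulli naive Bayes: priors P(y=c) and p[k, c] = P(x_k=1 | y=c)."""

    D: int
    priors: np.ndarray  # (2,)
    p: np.ndarray  # (D, 2)
    n_train: np.ndarray  # (2,) samples per class


@dataclass(frozen=True)
class LutModel:
    """Integer-cost twin of a :class:`BnbcModel`.

    ``cost_active[k, c]`` is the cost paid when x_k = 1, ``cost_inactive``
    when x_k = 0; ``prior_cost`` holds LUT(P(y=c)).  ``active_only``
    restricts the sum to active dimensions (dropping the Bernoulli
    x_k = 0 term); the default keeps both terms, matching the exact
    log-posterior.
    """

    D: int
    entries: np.ndarray  # (100,) costs per probability bin
    cost_active: np.ndarray  # (D, 2)
    cost_inactive: np.ndarray  # (D, 2)
    prior_cost: np.ndarray  # (2,)
    active_only: bool = False
    scale: int = LUT_SCALE
    bin_width: float = LUT_BIN_WIDTH


def fit(X, y) -> BnbcModel:
    """Estimate priors and Bernoulli probabilities by counting.

    X: N × D binary matrix; y: N labels in {0, 1}, both classes present.
    No smoothing is applied — empirical zeros and ones are kept and
    guarded downstream by the LUT offset.
    """
    X = np.asarray(X)
    y = np.asarray(y).astype(np.int64).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be N × D with one label per row")
    if not np.isin(X, (0, 1)).all():
        raise ValueError("X must be binary")
    counts = np.array([(y == 0).sum(), (y == 1).sum()], dtype=np.int64)
    if (counts == 0).any():
        raise ValueError("training data must contain both classes")
    d = X.shape[1]
    p = np.empty((d, 2), dtype=np.float64)
    for c in (0, 1):
        p[:, c] = X[y == c].mean(axis=0)
    return BnbcModel(D=d, priors=counts / counts.sum(), p=p, n_train=counts)


def _guarded_log(p: np.ndarray) -> np.ndarray:
    # Mirror the LUT's zero guard so both inference paths are comparable.
    return np.log(np.where(p <= LUT_CLAMP, p + LUT_LOG_OFFSET, p))


def log_posteriors(model: BnbcModel, X) -> np.ndarray:
    """Unnormalized log-posteriors, one row per sample, columns = classes."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.D:
        raise ValueError(f"expected D={model.D} features, got {X.shape[1]}")
    log_p = _guarded_log(model.p)
    log_q = _guarded_log(1.0 - model.p)
    out = _guarded_log(model.priors)[None, :] + X @ log_p + (1.0 - X) @ log_q
    return out


def predict_float(model: BnbcModel, x) -> tuple[int, np.ndarray]:
    """Exact (floating-point) classification of one binary vector.

    Returns (label, log-posteriors); a tie resolves to class 0
    (inter-ictal), the conservative choice against false alarms.
    """
    lp = log_posteriors(model, x)[0]
    label = 1 if lp[1] > lp[0] else 0
    return label, lp


def predict_float_batch(model: BnbcModel, X) -> np.ndarray:
    lp = log_posteriors(model, X)
    return (lp[:, 1] > lp[:, 0]).astype(np.int8)


def lut_entry(bin_index: int) -> int:
    """Integer cost for probability bin ``bin_index`` (1-based, 1..100).

    Bin b covers [(b−1)/100, b/100]; bins at or below 0.99 cost
    round(−128 · ln(lower edge + 0.001)); the top bin clamps to 1.
    """
    if not 1 <= bin_index <= N_LUT_BINS:
        raise ValueError(f"bin index {bin_index} outside 1..{N_LUT_BINS}")
    if bin_index == N_LUT_BINS:
        return 1
    p_low = (bin_index - 1) * LUT_BIN_WIDTH
    # round half away from zero (values are positive, so +0.5 and floor)
    return int(math.floor(-LUT_SCALE * math.log(p_low + LUT_LOG_OFFSET) + 0.5))


def lut_table() -> np.ndarray:
    """All 100 LUT entries, index 0 = bin 1."""
    return np.array([lut_entry(b) for b in range(1, N_LUT_BINS + 1)],
                    dtype=np.int64)


def quantize_bin(p) -> np.ndarray:
    """Map probabilities to 1-based bin indices; p = 1 lands in bin 100."""
    p = np.asarray(p, dtype=np.float64)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return np.minimum(np.floor(p / LUT_BIN_WIDTH).astype(np.int64) + 1,
                      N_LUT_BINS)


def build_lut(model: BnbcModel, active_only: bool = False) -> LutModel:
    """Quantize a fitted model's probabilities into integer cost arrays."""
    entries = lut_table()
    cost_active = entries[quantize_bin(model.p) - 1]
    cost_inactive = entries[quantize_bin(1.0 - model.p) - 1]
    prior_cost = entries[quantize_bin(model.priors) - 1]
    return LutModel(
        D=model.D,
        entries=entries,
        cost_active=cost_active,
        cost_inactive=cost_inactive,
        prior_cost=prior_cost,
        active_only=active_only,
    )


def lut_costs(lut: LutModel, X, active_only: bool | None = None) -> np.ndarray:
    """Accumulated integer costs, one row per sample, columns = classes."""
    X = np.atleast_2d(np.asarray(X, dtype=np.int64))
    if X.shape[1] != lut.D:
        raise ValueError(f"expected D={lut.D} features, got {X.shape[1]}")
    if active_only is None:
        active_only = lut.active_only
    costs = lut.prior_cost[None, :] + X @ lut.cost_active
    if not active_only:
        costs = costs + (1 - X) @ lut.cost_inactive
    return costs


def predict_lut(lut: LutModel, x, active_only: bool | None = None
                ) -> tuple[int, np.ndarray]:
    """Integer-cost classification: smallest accumulated cost wins, a tie
    resolves to class 0."""
    c = lut_costs(lut, x, active_only)[0]
    label = 1 if c[1] < c[0] else 0
    return label, c


def predict_lut_batch(lut: LutModel, X, active_only: bool | None = None
                      ) -> np.ndarray:
    c = lut_costs(lut, X, active_only)
    return (c[:, 1] < c[:, 0]).astype(np.int8)


def save_model(
    model: BnbcModel,
    path: str | Path,
    lut: LutModel | None = None,
    metadata: dict | None = None,
) -> None:
    """Serialize a fitted model (and optional LUT twin) as self-describing
    JSON; floats round-trip bit-exactly via repr."""
    payload: dict = {
        "format": "hdseizure-bnbc-v1",
        "D": model.D,
        "priors": model.priors.tolist(),
        "p": model.p.tolist(),
        "n_train": model.n_train.tolist(),
        "metadata": metadata or {},
    }
    if lut is not None:
        payload["lut"] = {
            "entries": lut.entries.tolist(),
            "cost_active": lut.cost_active.tolist(),
            "cost_inactive": lut.cost_inactive.tolist(),
            "prior_cost": lut.prior_cost.tolist(),
            "active_only": lut.active_only,
            "scale": lut.scale,
            "bin_width": lut.bin_width,
        }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path
               ) -> tuple[BnbcModel, LutModel | None, dict]:
    payload = json.loads(Path(path).read_text())
    model = BnbcModel(
        D=payload["D"],
        priors=np.array(payload["priors"], dtype=np.float64),
        p=np.array(payload["p"], dtype=np.float64),
        n_train=np.array(payload["n_train"], dtype=np.int64),
    )
    lut = None
    if "lut" in payload:
        lp = payload["lut"]
        lut = LutModel(
            D=model.D,
            entries=np.array(lp["entries"], dtype=np.int64),
            cost_active=np.array(lp["cost_active"], dtype=np.int64),
            cost_inactive=np.array(lp["cost_inactive"], dtype=np.int64),
            prior_cost=np.array(lp["prior_cost"], dtype=np.int64),
            active_only=lp["active_only"],
            scale=lp["scale"],
            bin_width=lp["bin_width"],
        )
    return model, lut, payload.get("metadata", {})
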