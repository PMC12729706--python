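"""Leave-one-seizure-out evaluation harness, metrics, and the storage
footprint model.

Splitting follows the per-patient protocol: each fold trains on TrS
seizure recordings (their ictal windows plus their own inter-ictal
windows) and tests on the remaining recordings.  One-shot means TrS = 1.

Sensitivity, specificity, and accuracy are window-level, computed on raw
per-window predictions before voting; detection latency is computed on
the voted output.  Post-ictal windows are excluded from the inter-ictal
class by default (configurable), since the class protocol defines
inter-ictal data as the pre-ictal period paired with each seizure.

The storage model itemises the bytes a fixed-point embedded
implementation needs — sample buffer, LBP registers, both hypervector
banks, bundling counters, class histogram, and the integer LUT — using
the printed bit widths of the reference design (7-bit spatial counters,
5-bit temporal counters, 6-bit histogram bins, 7-bit per-dimension costs,
10-bit LUT entries).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from .bnbc import build_lut, fit, predict_float_batch, predict_lut_batch
from .hdc import build_item_memory, encode_stream_hv
from .lbp import encode_recording
from .postprocess import DetectionOutcome, VotingConfig, detect, vote
from .signal_model import Recording, WindowGrid, window_labels, window_phases


@dataclass(frozen=True)
class SplitSpec:
    """Cross-validation layout: N seizures, TrS per training fold, K folds."""

    n_seizures: int
    n_train: int = 1
    n_folds: int | None = None
    mode: str = "one_shot"

    def __post_init__(self) -> None:
        if self.mode not in ("one_shot", "few_shot"):
            raise ValueError("mode must be one_shot or few_shot")
        if self.mode == "one_shot" and self.n_train != 1:
            raise ValueError("one_shot requires n_train = 1")
        if self.n_train >= self.n_seizures:
            raise ValueError("need at least one held-out seizure per fold")

    @property
    def k(self) -> int:
        return self.n_folds if self.n_folds is not None else self.n_seizures


def make_splits(recordings, spec: SplitSpec, seed: int
                ) -> list[tuple[list[int], list[int]]]:
    """Deterministic (train ids, test ids) folds over seizure recordings.

    ``recordings`` may be a list of recordings or an integer count.  With
    K = N in one-shot mode each fold trains on one distinct seizure; in
    few-shot mode the TrS-subsets are drawn without replacement from a
    seeded shuffle of all combinations.
    """
    n = recordings if isinstance(recordings, int) else len(recordings)
    if n != spec.n_seizures:
        raise ValueError(f"expected {spec.n_seizures} recordings, got {n}")
    k = spec.k
    rng = np.random.default_rng(seed)
    ids = list(range(n))
    if spec.mode == "one_shot":
        train_sets = [[i] for i in ids]
        if k < n:
            order = rng.permutation(n)[:k]
            train_sets = [[int(i)] for i in order]
        elif k > n:
            raise ValueError("one_shot cannot have more folds than seizures")
    else:
        n_combos = comb(n, spec.n_train)
        if k > n_combos:
            raise ValueError(
                f"cannot build {k} distinct folds from {n_combos} subsets"
            )
        combos = list(combinations(ids, spec.n_train))
        order = rng.permutation(len(combos))[:k]
        train_sets = [list(combos[i]) for i in order]
    return [
        (train, [i for i in ids if i not in train]) for train in train_sets
    ]


@dataclass
class FoldResult:
    """One fold's confusion counts and per-test-seizure outcomes."""

    train_ids: list[int]
    test_ids: list[int]
    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0
    outcomes: list[DetectionOutcome] = field(default_factory=list)


@dataclass
class MetricsReport:
    """Window-level classification metrics plus voted detection latency."""

    sensitivity_pct: float
    specificity_pct: float
    accuracy_pct: float
    mean_latency_s: float | None
    n_detected: int
    n_missed: int
    tp: int
    fn: int
    tn: int
    fp: int
    per_fold: list[FoldResult] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = self.tp + self.fn + self.tn + self.fp
        if total:
            acc = 100.0 * (self.tp + self.tn) / total
            if abs(acc - self.accuracy_pct) > 1e-9:
                raise ValueError("accuracy inconsistent with confusion counts")


def _pct(num: int, den: int) -> float:
    return 100.0 * num / den if den else float("nan")


def compute_metrics(pred_labels, true_labels,
                    outcomes: list[DetectionOutcome] | None = None,
                    per_fold: list[FoldResult] | None = None) -> MetricsReport:
    """Confusion-based metrics over aligned window label vectors.

    sensitivity = TP/(TP+FN) over ictal windows, specificity = TN/(TN+FP)
    over inter-ictal windows, accuracy over all; mean latency averages the
    voted outcomes of detected seizures only.
    """
    pred = np.asarray(pred_labels, dtype=np.int64).ravel()
    true = np.asarray(true_labels, dtype=np.int64).ravel()
    if pred.shape != true.shape:
        raise ValueError("prediction/label length mismatch")
    tp = int(((pred == 1) & (true == 1)).sum())
    fn = int(((pred == 0) & (true == 1)).sum())
    tn = int(((pred == 0) & (true == 0)).sum())
    fp = int(((pred == 1) & (true == 0)).sum())
    outcomes = outcomes or []
    latencies = [o.latency_s for o in outcomes if o.latency_s is not None]
    return MetricsReport(
        sensitivity_pct=_pct(tp, tp + fn),
        specificity_pct=_pct(tn, tn + fp),
        accuracy_pct=_pct(tp + tn, tp + fn + tn + fp),
        mean_latency_s=float(np.mean(latencies)) if latencies else None,
        n_detected=len(latencies),
        n_missed=len(outcomes) - len(latencies),
        tp=tp, fn=fn, tn=tn, fp=fp,
        per_fold=per_fold or [],
    )


def cross_validate(
    recordings: list[Recording],
    spec: SplitSpec,
    D: int = 1000,
    window_s: float = 0.25,
    seed: int = 0,
    use_lut: bool = False,
    active_only: bool = False,
    t_p: int | None = None,
    vote_window_s: float = 5.0,
    exclude_postictal: bool = True,
) -> MetricsReport:
    """Run the full detector over leave-one-seizure-out folds.

    Builds one item memory for the patient, encodes every recording once,
    then per fold fits the classifier on the training recordings' windows
    and scores the held-out recordings (window metrics on raw predictions,
    latency on the voted output).
    """
    if not recordings:
        raise ValueError("no recordings")
    m = recordings[0].n_channels
    if any(r.n_channels != m for r in recordings):
        raise ValueError("all recordings must share the electrode count")
    im = build_item_memory(D, m, seed)

    encoded = []
    for rec in recordings:
        grid = WindowGrid.from_recording(rec, window_s)
        X = encode_stream_hv(encode_recording(rec), im, grid)
        encoded.append(
            (X, window_labels(rec, grid), window_phases(rec, grid), rec)
        )

    vcfg = VotingConfig(window_s=window_s, vote_window_s=vote_window_s, t_p=t_p)
    folds = make_splits(len(recordings), spec, seed)
    all_pred, all_true, all_outcomes = [], [], []
    fold_results = []
    for train_ids, test_ids in folds:
        Xtr, ytr = [], []
        for i in train_ids:
            X, labels, phases, _ = encoded[i]
            keep = phases != 2 if exclude_postictal else slice(None)
            Xtr.append(X[keep])
            ytr.append(labels[keep])
        model = fit(np.concatenate(Xtr), np.concatenate(ytr))
        lut = build_lut(model, active_only=active_only) if use_lut else None

        fr = FoldResult(train_ids=list(train_ids), test_ids=list(test_ids))
        for i in test_ids:
            X, labels, phases, rec = encoded[i]
            pred = (predict_lut_batch(lut, X) if use_lut
                    else predict_float_batch(model, X))
            keep = phases != 2 if exclude_postictal else np.ones(
                labels.size, dtype=bool)
            all_pred.append(pred[keep])
            all_true.append(labels[keep])
            fr.tp += int(((pred == 1) & (labels == 1))[keep].sum())
            fr.fn += int(((pred == 0) & (labels == 1))[keep].sum())
            fr.tn += int(((pred == 0) & (labels == 0))[keep].sum())
            fr.fp += int(((pred == 1) & (labels == 0))[keep].sum())
            outcome = detect(vote(pred, vcfg), rec.annotations, vcfg)
            fr.outcomes.append(outcome)
            all_outcomes.append(outcome)
        fold_results.append(fr)

    return compute_metrics(
        np.concatenate(all_pred), np.concatenate(all_true),
        all_outcomes, fold_results,
    )


@dataclass(frozen=True)
class StorageConfig:
    """Bit widths and sizes for the embedded storage model.

    Defaults describe the 0.25 s / D=1000 configuration of a 100-electrode
    patient with a 16-bit ADC.
    """

    n_electrodes: int = 100
    D: int = 1000
    adc_bits: int = 16
    lbp_points: int = 7
    lbp_bits: int = 6
    n_codes: int = 64
    xor_counter_bits: int = 7
    window_counter_bits: int = 5
    histogram_bits: int = 6
    lut_cost_bits: int = 7
    lut_entry_bits: int = 10
    n_lut_entries: int = 100
    misc_bytes: float = 10.5


def storage_report(config: StorageConfig = StorageConfig()) -> dict:
    """Itemised storage requirement in bits and bytes (bits / 8).

    Returns {component: {"bits": int, "bytes": float}} plus "total_bytes".
    With the defaults the total is 25,235.5 bytes (~25.24 KB).
    """
    c = config
    bits = {
        "sample_buffer": c.adc_bits * c.lbp_points * c.n_electrodes,
        "lbp_values": 1 * c.lbp_bits * c.n_electrodes,
        "code_matrix": c.D * c.n_codes,
        "electrode_matrix": c.D * c.n_electrodes,
        "xor_sum_counters": c.xor_counter_bits * c.D,
        "window_counters": c.window_counter_bits * c.D,
        "histogram": c.histogram_bits * c.D,
        "lut": c.lut_cost_bits * c.D + c.lut_entry_bits * c.n_lut_entries,
    }
    report: dict = {
        name: {"bits": b, "bytes": b / 8} for name, b in bits.items()
    }
    report["misc"] = {"bits": None, "bytes": c.misc_bytes}
    report["total_bytes"] = sum(b / 8 for b in bits.values()) + c.misc_bytes
    return report
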