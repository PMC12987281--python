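"""Windowing, balancing, standardization and stratified splitting.

Converts labeled 100 Hz pressure streams into fixed-length training
windows: an optional below-threshold filter isolating active squats from
rest periods, sliding-window segmentation (500 ms windows by default) with
majority-vote labels, per-class up/down-sampling to an exactly balanced
dataset, a per-class 80/20 stratified split, and global scalar Z-score
standardization fitted on the training portion only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .synth import PressureTrace

__all__ = [
    "LabeledWindow",
    "DatasetSplit",
    "threshold_filter",
    "segment_windows",
    "balance_classes",
    "standardize",
    "stratified_split",
    "prepare_dataset",
    "windows_to_arrays",
]

DEFAULT_WINDOW_SAMPLES = 50   # 500 ms at 100 Hz
DEFAULT_STRIDE_SAMPLES = 5    # 50 ms


@dataclass(frozen=True)
class LabeledWindow:
    """Fixed-length pressure window with its activity label."""

    samples: np.ndarray
    label: str
    source_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))


@dataclass
class DatasetSplit:
    """Disjoint train/test window arrays plus the fitted standardization.

    ``train_X``/``test_X`` are ``(n, window_len)`` float arrays, labels are
    string arrays; ``standardization`` is the global scalar ``(mean, sd)``
    fitted on the training portion and applied to both.
    """

    train_X: np.ndarray
    train_y: np.ndarray
    test_X: np.ndarray
    test_y: np.ndarray
    standardization: Optional[tuple[float, float]] = None
    class_counts: dict = field(default_factory=dict)

    def save(self, path) -> None:
        mean, sd = self.standardization if self.standardization else (np.nan, np.nan)
        np.savez(
            path,
            train_X=self.train_X, train_y=self.train_y.astype(str),
            test_X=self.test_X, test_y=self.test_y.astype(str),
            standardization=np.array([mean, sd]),
        )

    @classmethod
    def load(cls, path) -> "DatasetSplit":
        with np.load(path, allow_pickle=False) as z:
            mean, sd = z["standardization"]
            std = None if np.isnan(mean) else (float(mean), float(sd))
            train_y = z["train_y"].astype(object)
            test_y = z["test_y"].astype(object)
            split = cls(z["train_X"], train_y, z["test_X"], test_y, std)
        labels, counts = np.unique(np.concatenate([split.train_y, split.test_y]),
                                   return_counts=True)
        split.class_counts = dict(zip(labels.tolist(), counts.tolist()))
        return split


def threshold_filter(trace: PressureTrace, threshold_kpa: float) -> PressureTrace:
    """Drop samples strictly below ``threshold_kpa``.

    Used on squat recordings to discard the between-repetition rest periods,
    whose pressure sits at (or below) the static baseline and would
    otherwise be mislabeled standing-like data.
    """
    if threshold_kpa <= 0:
        raise ValueError("threshold_kpa must be > 0")
    keep = trace.values >= threshold_kpa
    if not keep.any():
        warnings.warn("threshold_filter removed every sample", stacklevel=2)
    labels = trace.labels[keep] if trace.labels is not None else None
    meta = dict(trace.meta, threshold_kpa=threshold_kpa)
    return PressureTrace(values=trace.values[keep],
                         sampling_rate_hz=trace.sampling_rate_hz,
                         labels=labels, meta=meta)


def segment_windows(
    trace: PressureTrace,
    window_len_samples: int = DEFAULT_WINDOW_SAMPLES,
    stride_samples: int = DEFAULT_STRIDE_SAMPLES,
    source_id: str = "",
) -> list[LabeledWindow]:
    """Slide a fixed window over the trace; majority-vote per-window labels.

    Window count before label filtering is ``floor((N - w) / stride) + 1``.
    A window's label is the sample label covering at least half the window;
    boundary-spanning windows with no such majority are dropped rather than
    mislabeled.
    """
    if window_len_samples < 1 or stride_samples < 1:
        raise ValueError("window and stride must be >= 1 sample")
    n = len(trace)
    if n < window_len_samples:
        return []
    if trace.labels is None:
        raise ValueError("segment_windows requires a labeled trace")
    out: list[LabeledWindow] = []
    half = window_len_samples / 2.0
    for i, start in enumerate(range(0, n - window_len_samples + 1, stride_samples)):
        sl = slice(start, start + window_len_samples)
        labels, counts = np.unique(trace.labels[sl], return_counts=True)
        j = int(np.argmax(counts))
        if counts[j] >= half:
            out.append(LabeledWindow(trace.values[sl], str(labels[j]),
                                     source_id=f"{source_id}:{start}"))
    return out


def balance_classes(
    windows: Sequence[LabeledWindow], target_per_class: int, seed: int,
    required_classes: Optional[Sequence[str]] = None,
) -> list[LabeledWindow]:
    """Resample each class to exactly ``target_per_class`` windows.

    Classes above target are down-sampled without replacement; classes below
    are up-sampled with replacement.  When ``required_classes`` is given,
    every listed class must be present in the input.  Deterministic given
    ``seed``.
    """
    if target_per_class < 1:
        raise ValueError("target_per_class must be >= 1")
    by_class: dict[str, list[LabeledWindow]] = {}
    for w in windows:
        by_class.setdefault(w.label, []).append(w)
    if required_classes is not None:
        missing = sorted(set(required_classes) - set(by_class))
        if missing:
            raise ValueError(f"classes absent from the window set: {missing}")
    if not by_class:
        raise ValueError("no windows to balance")
    rng = np.random.default_rng(seed)
    out: list[LabeledWindow] = []
    for label in sorted(by_class):
        pool = by_class[label]
        if len(pool) >= target_per_class:
            idx = rng.choice(len(pool), size=target_per_class, replace=False)
        else:
            idx = rng.choice(len(pool), size=target_per_class, replace=True)
        out.extend(pool[i] for i in idx)
    return out


def standardize(
    windows: Sequence[LabeledWindow], fitted_on: Optional[tuple[float, float]] = None
) -> tuple[list[LabeledWindow], tuple[float, float]]:
    """Global scalar Z-score: ``(x - mean) / sd``.

    When ``fitted_on`` is None the scalar mean/sd are fitted on the given
    windows (the training portion); otherwise the supplied parameters are
    applied unchanged (the test portion).
    """
    X = np.stack([w.samples for w in windows])
    if fitted_on is None:
        mean = float(X.mean())
        sd = float(X.std())
        if sd == 0.0:
            raise ValueError("zero variance: cannot standardize a constant dataset")
    else:
        mean, sd = fitted_on
        if sd == 0.0:
            raise ValueError("standardization sd must be non-zero")
    Z = (X - mean) / sd
    out = [LabeledWindow(z, w.label, w.source_id) for z, w in zip(Z, windows)]
    return out, (mean, sd)


def stratified_split(
    windows: Sequence[LabeledWindow], ratio: float = 0.8, seed: int = 0,
    min_per_class: int = 5,
) -> tuple[list[LabeledWindow], list[LabeledWindow]]:
    """Seeded per-class partition into train/test at ``ratio`` (floor on test).

    Each class is shuffled independently and split so the test side gets
    ``floor(n_class * (1 - ratio))`` windows, keeping the class proportions
    of train and test within one window of each other.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    by_class: dict[str, list[LabeledWindow]] = {}
    for w in windows:
        by_class.setdefault(w.label, []).append(w)
    for label, pool in by_class.items():
        if len(pool) < min_per_class:
            raise ValueError(f"class {label!r} has {len(pool)} windows; "
                             f"need >= {min_per_class}")
    rng = np.random.default_rng(seed)
    train: list[LabeledWindow] = []
    test: list[LabeledWindow] = []
    for label in sorted(by_class):
        pool = by_class[label]
        order = rng.permutation(len(pool))
        # tiny epsilon guards against float artifacts (e.g. 600*0.2 = 119.999...)
        n_test = int(np.floor(len(pool) * (1.0 - ratio) + 1e-9))
        test.extend(pool[i] for i in order[:n_test])
        train.extend(pool[i] for i in order[n_test:])
    return train, test


def windows_to_arrays(windows: Sequence[LabeledWindow]) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into an ``(n, L)`` array and an object array of labels."""
    X = np.stack([w.samples for w in windows])
    y = np.array([w.label for w in windows], dtype=object)
    return X, y


def prepare_dataset(
    trace: PressureTrace,
    window_len_samples: int = DEFAULT_WINDOW_SAMPLES,
    stride_samples: int = DEFAULT_STRIDE_SAMPLES,
    target_per_class: Optional[int] = None,
    split_ratio: float = 0.8,
    seed: int = 0,
    squat_threshold_kpa: Optional[float] = None,
) -> DatasetSplit:
    """Full stream-to-dataset pipeline.

    Order: squat-only threshold filter -> windowing -> class balancing ->
    stratified split -> Z-score fitted on train, applied to both.  The squat
    filter removes squat-labeled samples below ``squat_threshold_kpa``
    (typically the static baseline) before windowing; other labels pass
    through untouched.
    """
    if squat_threshold_kpa is not None and trace.labels is not None:
        squat = trace.labels == "squatting"
        keep = ~squat | (trace.values >= squat_threshold_kpa)
        trace = PressureTrace(values=trace.values[keep],
                              sampling_rate_hz=trace.sampling_rate_hz,
                              labels=trace.labels[keep], meta=dict(trace.meta))
    ss = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    windows = segment_windows(trace, window_len_samples, stride_samples)
    if not windows:
        raise ValueError("trace produced no windows")
    if target_per_class is None:
        counts = np.unique([w.label for w in windows], return_counts=True)[1]
        target_per_class = int(counts.min())
    windows = balance_classes(windows, target_per_class, seed=int(ss[0]))
    train_w, test_w = stratified_split(windows, ratio=split_ratio, seed=int(ss[1]))
    train_w, params = standardize(train_w)
    test_w, _ = standardize(test_w, fitted_on=params)
    train_X, train_y = windows_to_arrays(train_w)
    test_X, test_y = windows_to_arrays(test_w)
    labels, counts = np.unique(np.concatenate([train_y, test_y]), return_counts=True)
    return DatasetSplit(train_X, train_y, test_X, test_y, params,
                        dict(zip(labels.tolist(), counts.tolist())))
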