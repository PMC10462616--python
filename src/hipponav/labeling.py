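"""Speed labelling schemes: extreme deciles and 10-unit bins.

Two labelings feed the decoders: a balanced binary task contrasting the
slowest versus fastest fraction of windows, and five equal-width speed
bins with one binary task per unordered bin pair.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import FeatureTable

__all__ = [
    "LabeledDataset",
    "PairwiseTask",
    "extreme_decile_labels",
    "discretize_bins",
    "pairwise_tasks",
]

log = logging.getLogger(__name__)


@dataclass
class LabeledDataset:
    """Feature rows paired with class labels (binary or bin index)."""

    features: np.ndarray  # (n, p)
    labels: np.ndarray  # (n,) int
    window_index: np.ndarray  # (n,) original FeatureTable row indices
    scheme: str  # "decile" | "bins" | "pair"

    def __post_init__(self) -> None:
        if not (len(self.features) == len(self.labels) == len(self.window_index)):
            raise ValueError("features, labels and window_index must align")

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


@dataclass(frozen=True)
class PairwiseTask:
    """Binary discrimination between two speed bins."""

    bin_lo: int
    bin_hi: int
    gap: float  # units/s, midpoint difference between the two bins

    def __post_init__(self) -> None:
        if not self.bin_lo < self.bin_hi:
            raise ValueError("need bin_lo < bin_hi")

    @property
    def name(self) -> str:
        return f"bin{self.bin_lo}_vs_bin{self.bin_hi}"


def extreme_decile_labels(
    table: FeatureTable, fraction: float = 0.10
) -> LabeledDataset:
    """Label the slowest ``fraction`` of windows 0 and the fastest 1.

    Each class receives exactly ``floor(fraction * N)`` windows; all other
    windows are dropped.  Rows are ranked by window-mean speed with ties
    broken in favour of earlier windows; if the slow and fast selections
    would overlap (massively tied speeds), the fast class is filled from
    the remaining rows in rank order and a warning is logged.
    """
    n = table.n_windows
    n_per = int(np.floor(fraction * n))
    if n_per < 1 or 2 * n_per > n:
        raise ValueError(
            f"too few windows ({n}) for fraction {fraction}: "
            f"need floor(fraction*N) >= 1 and 2*floor(fraction*N) <= N"
        )
    speed = np.asarray(table.speed, dtype=float)
    asc = np.argsort(speed, kind="stable")  # ties -> earlier window first
    desc = np.argsort(-speed, kind="stable")
    slow = asc[:n_per]
    slow_set = set(slow.tolist())
    fast_list: list[int] = []
    for i in desc:
        if int(i) not in slow_set:
            fast_list.append(int(i))
            if len(fast_list) == n_per:
                break
    fast = np.asarray(fast_list, dtype=int)
    if speed[fast].min() <= speed[slow].max():
        log.warning(
            "slow/fast speed ranges touch (tied speeds at the decile "
            "boundary); classes assigned by time order among ties"
        )
    idx = np.concatenate([slow, fast])
    labels = np.concatenate([np.zeros(n_per, dtype=int), np.ones(n_per, dtype=int)])
    order = np.argsort(idx, kind="stable")  # keep time order in the output
    return LabeledDataset(
        features=table.features[idx[order]],
        labels=labels[order],
        window_index=idx[order],
        scheme="decile",
    )


def discretize_bins(
    table: FeatureTable, bin_width: float = 10.0, v_max: float = 50.0
) -> LabeledDataset:
    """Assign every window to an equal-width speed bin.

    Bin k covers [k*w, (k+1)*w) except the last bin, which is closed at
    ``v_max``.
    """
    speed = np.asarray(table.speed, dtype=float)
    if speed.min() < 0 or speed.max() > v_max:
        raise ValueError(
            f"speeds outside [0, {v_max}]: range "
            f"[{speed.min():.3f}, {speed.max():.3f}]"
        )
    n_bins = int(round(v_max / bin_width))
    labels = np.minimum(np.floor(speed / bin_width).astype(int), n_bins - 1)
    return LabeledDataset(
        features=table.features,
        labels=labels,
        window_index=np.arange(table.n_windows),
        scheme="bins",
    )


def pairwise_tasks(
    dataset: LabeledDataset, bin_width: float = 10.0, min_per_bin: int = 2
) -> list[tuple[PairwiseTask, LabeledDataset]]:
    """One binary task per unordered pair of populated speed bins.

    Bins with fewer than ``min_per_bin`` windows are skipped with a
    warning.  Each task's dataset keeps that pair's windows only, with
    the slower bin labelled 0 and the faster 1 (natural, unbalanced
    sizes).
    """
    if dataset.scheme != "bins":
        raise ValueError("pairwise_tasks requires a bins-scheme dataset")
    counts = dataset.class_counts()
    usable = sorted(b for b, c in counts.items() if c >= min_per_bin)
    skipped = sorted(set(counts) - set(usable))
    if skipped:
        log.warning("skipping underpopulated bins %s (< %d windows)",
                    skipped, min_per_bin)
    out: list[tuple[PairwiseTask, LabeledDataset]] = []
    for lo, hi in itertools.combinations(usable, 2):
        task = PairwiseTask(bin_lo=lo, bin_hi=hi, gap=bin_width * (hi - lo))
        sel = np.flatnonzero((dataset.labels == lo) | (dataset.labels == hi))
        out.append(
            (
                task,
                LabeledDataset(
                    features=dataset.features[sel],
                    labels=(dataset.labels[sel] == hi).astype(int),
                    window_index=dataset.window_index[sel],
                    scheme="pair",
                ),
            )
        )
    return out
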