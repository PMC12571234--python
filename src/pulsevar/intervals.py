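"""Beat-to-beat interval series and the adaptive N-N artifact filter.

Raw peak-to-peak (P-P) intervals from a pressure waveform contain artifacts:
spurious detections produce implausibly short intervals, missed or ectopic
beats produce values far from the local mean.  The adaptive filter converts
P-P to normal-to-normal (N-N) intervals with two rules:

1. drop intervals shorter than 20 ms (incompatible with cardiac physiology);
2. drop intervals deviating from the moving-window mean by more than three
   moving-window standard deviations.

Rule 2 statistics are computed over a centered window of rule-1 survivors,
excluding the candidate itself so an extreme value cannot mask its own
rejection; both rules are decided against the rule-1 survivor series, not
sequentially, and rejected values are dropped (never interpolated).  A mask
over the parent P-P series records the reason for every rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["IntervalSeries", "AdaptiveFilterSettings", "adaptive_filter",
           "KEPT", "REJECTED_SHORT", "REJECTED_OUTLIER"]

KEPT = "kept"
REJECTED_SHORT = "rejected_short"
REJECTED_OUTLIER = "rejected_outlier"


@dataclass
class IntervalSeries:
    """Beat-to-beat intervals in milliseconds.

    Parameters
    ----------
    values : ndarray
        Interval durations, ms; all positive.
    timestamps : ndarray
        End-of-interval times, seconds; strictly increasing.
    kind : {"PP", "NN"}
        Raw peak-to-peak or artifact-filtered normal-to-normal.
    rejection_mask : ndarray of str, optional
        For an NN series: one entry per *parent* P-P interval, each one of
        ``kept`` / ``rejected_short`` / ``rejected_outlier``.
    parent_index : ndarray of int, optional
        For each kept value, its index in the parent P-P series.  Used to
        identify originally adjacent pairs for successive-difference
        statistics.  Defaults to 0..n-1 (every pair adjacent).
    """

    values: np.ndarray
    timestamps: np.ndarray
    kind: str = "PP"
    rejection_mask: Optional[np.ndarray] = None
    parent_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.values.shape != self.timestamps.shape or self.values.ndim != 1:
            raise ValueError("values and timestamps must be 1-D arrays of equal length")
        if np.any(self.values <= 0):
            raise ValueError("interval values must be positive")
        if self.values.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.kind not in ("PP", "NN"):
            raise ValueError(f"kind must be 'PP' or 'NN', got {self.kind!r}")
        if self.parent_index is None:
            self.parent_index = np.arange(self.values.size)
        else:
            self.parent_index = np.asarray(self.parent_index, dtype=int)
            if self.parent_index.shape != self.values.shape:
                raise ValueError("parent_index must match values in shape")
        if self.rejection_mask is not None:
            self.rejection_mask = np.asarray(self.rejection_mask)
            if self.kind == "NN" and np.count_nonzero(self.rejection_mask == KEPT) != self.values.size:
                raise ValueError("rejection_mask 'kept' count must equal the number of values")

    def __len__(self) -> int:
        return self.values.size

    @property
    def span(self) -> float:
        """Time covered by the series, first to last timestamp, seconds."""
        return float(self.timestamps[-1] - self.timestamps[0]) if len(self) else 0.0


@dataclass(frozen=True)
class AdaptiveFilterSettings:
    """Adaptive N-N rejection thresholds.

    min_interval : float
        Rule-1 floor in ms (default 20).
    sd_multiplier : float
        Rule-2 threshold in moving-window standard deviations (default 3).
    moving_window : int
        Centered window length in intervals for rule-2 statistics; odd,
        >= 5 (default 31, ~15-20 s of context at porcine rates).
    """

    min_interval: float = 20.0
    sd_multiplier: float = 3.0
    moving_window: int = 31

    def __post_init__(self) -> None:
        if not self.min_interval > 0:
            raise ValueError("min_interval must be positive")
        if not self.sd_multiplier > 0:
            raise ValueError("sd_multiplier must be positive")
        if self.moving_window < 5 or self.moving_window % 2 == 0:
            raise ValueError("moving_window must be odd and >= 5")


def adaptive_filter(pp: IntervalSeries,
                    settings: AdaptiveFilterSettings = AdaptiveFilterSettings()
                    ) -> IntervalSeries:
    """Filter a P-P series to N-N, recording per-interval rejection reasons.

    The moving window is truncated at the series edges.  A degenerate window
    (constant survivors, sd = 0) would reject any value that differs at all
    from the window mean; the standard deviation is therefore floored at
    1 ms so measurement-precision jitter is never rejected.

    Raises
    ------
    ValueError
        If ``pp`` is not a P-P series, is shorter than the moving window,
        or if every interval ends up rejected.
    """
    if pp.kind != "PP":
        raise ValueError(f"adaptive_filter expects a PP series, got kind={pp.kind!r}")
    n = len(pp)
    if n < settings.moving_window:
        raise ValueError(
            f"series of {n} intervals is shorter than the moving window "
            f"({settings.moving_window})"
        )

    v = pp.values
    mask = np.full(n, KEPT, dtype="<U16")
    mask[v < settings.min_interval] = REJECTED_SHORT

    surv = np.flatnonzero(mask == KEPT)
    sv = v[surv]
    half = settings.moving_window // 2
    m = sv.size
    reject = np.zeros(m, dtype=bool)
    for j in range(m):
        lo = max(0, j - half)
        hi = min(m, j + half + 1)
        win = np.concatenate((sv[lo:j], sv[j + 1:hi]))
        if win.size < 2:
            continue
        mu = win.mean()
        sd = max(win.std(ddof=1), 1.0)
        if abs(sv[j] - mu) > settings.sd_multiplier * sd:
            reject[j] = True
    mask[surv[reject]] = REJECTED_OUTLIER

    kept = np.flatnonzero(mask == KEPT)
    if kept.size == 0:
        raise ValueError("adaptive filter rejected every interval")
    return IntervalSeries(
        values=v[kept],
        timestamps=pp.timestamps[kept],
        kind="NN",
        rejection_mask=mask,
        parent_index=pp.parent_index[kept],
    )
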