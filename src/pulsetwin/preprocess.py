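"""Filter-free four-stage pulse preprocessing.

The chain is: moving-mean detrending with normalisation, foot-point
detection with a minimum-interval gate, foot-to-foot segmentation into
single cycles, quadratic-spline resampling of each cycle to a fixed length,
and pointwise multicycle averaging.  No bandpass or low-pass filter is
applied anywhere: subject-specific high-frequency morphology is preserved
and uncorrelated noise is suppressed solely by averaging N cycles, which
scales its variance by 1/N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .records import SignalRecord


class TooFewCyclesError(ValueError):
    """A record did not yield enough complete cycles for the requested N."""

    def __init__(self, record_id: str, found: int, needed: int):
        self.record_id, self.found, self.needed = record_id, found, needed
        super().__init__(f"record {record_id!r}: found {found} complete cycles, need {needed}")


@dataclass(frozen=True)
class DetrendedSignal:
    """Zero-baseline dimensionless signal: (x - local mean) / local mean."""

    values: np.ndarray
    window_size: int
    record_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FootPoints:
    """Accepted pulse-onset minima, gated by a minimum interval."""

    indices: np.ndarray
    min_interval_samples: int

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.size and np.any(np.diff(idx) < self.min_interval_samples):
            raise ValueError("foot points violate the minimum interval")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class RawCycle:
    """One variable-length single-cycle segment [start_index, end_index)."""

    values: np.ndarray
    start_index: int
    end_index: int

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if self.end_index - self.start_index != len(values):
            raise ValueError("cycle span does not match its length")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ProcessedCycle:
    """A fixed-length averaged single-cycle template ready for the verifier."""

    values: np.ndarray
    n_averaged: int
    subject_id: str = ""
    record_id: str = ""

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError(f"cycle {self.record_id!r}: non-finite values")
        if self.n_averaged < 1:
            raise ValueError("n_averaged must be >= 1")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


def moving_mean(samples, window_size: int) -> np.ndarray:
    """Forward moving mean, truncated at the end of the signal.

    Element ``i`` is the mean of ``samples[i : i + window_size]``; windows
    that would run past the end simply average fewer samples, so the last
    element equals the last sample.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("moving_mean needs a non-empty 1-D sequence")
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    n = x.size
    csum = np.concatenate(([0.0], np.cumsum(x)))
    start = np.arange(n)
    stop = np.minimum(start + window_size, n)
    return (csum[stop] - csum[start]) / (stop - start)


def detrend_normalize(samples, window_size: int, record_id: str = "") -> DetrendedSignal:
    """Detrend and normalise: element i becomes (x_i - m_i) / m_i.

    ``m`` is the forward moving mean.  The division keeps amplitude
    information in relative units and brings the baseline to zero; it
    requires a nonzero local mean everywhere, which holds for raw PPG
    (strictly positive).
    """
    x = np.asarray(samples, dtype=float)
    m = moving_mean(x, window_size)
    bad = np.flatnonzero(m == 0.0)
    if bad.size:
        raise ZeroDivisionError(
            f"record {record_id!r}: zero local mean at index {int(bad[0])}; cannot normalise")
    return DetrendedSignal((x - m) / m, window_size, record_id)


def detect_foot_points(detrended: DetrendedSignal, min_interval_samples: int) -> FootPoints:
    """Find pulse feet: sub-zero local minima, greedily gated by interval.

    Candidates are turning points where the first difference changes from
    negative to non-negative and the value is below zero (the detrended
    baseline).  Scanning left to right, a candidate closer than
    ``min_interval_samples`` to the last accepted foot is discarded — this
    removes spurious notches that a filter would otherwise have smoothed
    away.  May return an empty set.
    """
    if min_interval_samples < 1:
        raise ValueError("min_interval_samples must be >= 1")
    v = detrended.values
    if v.size < 3:
        return FootPoints(np.empty(0, dtype=int), min_interval_samples)
    d = np.diff(v)
    cand = np.flatnonzero((d[:-1] < 0) & (d[1:] >= 0)) + 1
    cand = cand[v[cand] < 0]
    accepted: list[int] = []
    for i in cand:
        if not accepted or i - accepted[-1] >= min_interval_samples:
            accepted.append(int(i))
    return FootPoints(np.asarray(accepted, dtype=int), min_interval_samples)


def segment_cycles(detrended: DetrendedSignal, feet: FootPoints) -> list[RawCycle]:
    """Cut the signal between successive feet: k feet give k-1 cycles.

    Cycle j covers the half-open span [foot_j, foot_{j+1}); concatenating
    all cycles reproduces the signal between the first and last foot.
    Fewer than two feet yield an empty list.
    """
    idx = feet.indices
    cycles = []
    for a, b in zip(idx[:-1], idx[1:]):
        cycles.append(RawCycle(detrended.values[a:b], int(a), int(b)))
    return cycles


def _quadratic_spline_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Knot slopes Z of the quadratic spline with a zero initial slope.

    Z_0 = 0 and Z_{i+1} = 2 (y_{i+1} - y_i) / (x_{i+1} - x_i) - Z_i, which
    makes the piecewise quadratic C^1 across knots.
    """
    z = np.empty_like(y)
    z[0] = 0.0
    slopes = 2.0 * np.diff(y) / np.diff(x)
    # z[i+1] = slopes[i] - z[i]  -> alternating partial sums
    sign = np.ones(len(slopes))
    sign[1::2] = -1.0
    z[1:] = sign * np.cumsum(sign * slopes)
    return z


def resample_cycle(cycle: RawCycle | np.ndarray, cycle_length: int) -> np.ndarray:
    """Resample one cycle to ``cycle_length`` points by quadratic spline.

    On each knot interval the interpolant is
    ``S_i(t) = y_i + Z_i (t - x_i) + (Z_{i+1} - Z_i) / (2 (x_{i+1} - x_i)) (t - x_i)^2``,
    which passes through every knot exactly.  It is evaluated on a grid of
    ``cycle_length`` equally spaced points spanning the closed interval from
    the first to the last knot (endpoints included).
    """
    y = np.asarray(cycle.values if isinstance(cycle, RawCycle) else cycle, dtype=float)
    if y.size < 3:
        raise ValueError(f"cycle of length {y.size}: need >= 3 samples for the spline")
    if cycle_length < 2:
        raise ValueError("cycle_length must be >= 2")
    x = np.arange(y.size, dtype=float)
    z = _quadratic_spline_slopes(x, y)
    t = np.linspace(x[0], x[-1], cycle_length)
    seg = np.clip(np.searchsorted(x, t, side="right") - 1, 0, y.size - 2)
    dt = t - x[seg]
    h = x[seg + 1] - x[seg]
    return y[seg] + z[seg] * dt + (z[seg + 1] - z[seg]) / (2.0 * h) * dt ** 2


def multicycle_average(cycles, n: int, subject_id: str = "", record_id: str = "") -> ProcessedCycle:
    """Pointwise mean of the first ``n`` fixed-length cycles.

    Averaging N cycles of template-plus-independent-noise leaves the
    template untouched and divides the noise variance by N — the whole
    point of skipping frequency-domain filtering.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    arrays = [np.asarray(c, dtype=float) for c in cycles]
    if len(arrays) < n:
        raise TooFewCyclesError(record_id, len(arrays), n)
    lengths = {a.size for a in arrays[:n]}
    if len(lengths) != 1:
        raise ValueError(f"cycles of differing lengths {sorted(lengths)} cannot be averaged")
    stacked = np.stack(arrays[:n])
    return ProcessedCycle(stacked.mean(axis=0), n, subject_id, record_id)


def preprocess_record(record: SignalRecord, config: RunConfig) -> ProcessedCycle:
    """Full chain: detrend -> feet -> segment -> resample -> average.

    Produces exactly one fixed-length template per record from its first
    ``config.n_cycles`` complete cycles.  Raises
    :class:`TooFewCyclesError` when the record is too short or too noisy
    to supply that many cycles.
    """
    detrended = detrend_normalize(record.samples, config.window_size, record.record_id)
    feet = detect_foot_points(detrended, config.min_interval_samples)
    cycles = segment_cycles(detrended, feet)
    usable = [c for c in cycles if len(c) >= 3]
    if len(usable) < config.n_cycles:
        raise TooFewCyclesError(record.record_id, len(usable), config.n_cycles)
    resampled = [resample_cycle(c, config.cycle_length) for c in usable[: config.n_cycles]]
    return multicycle_average(resampled, config.n_cycles, record.subject_id, record.record_id)
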