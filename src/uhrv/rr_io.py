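"""Annotated RR-interval series: reading, writing, and the NN/RR quality gate.

An RR interval is the time between consecutive heartbeats; an NN interval is
an RR interval delimited by two normal (sinus) beats. HRV analysis operates on
NN intervals only. When ectopic-beat correction is not applied, the fraction
of intervals that are NN (the NN/RR ratio) serves as a signal-quality index:
records whose ratio falls below a threshold (90% here) are rejected rather
than repaired.

All times and intervals are milliseconds. ``beat_times`` are cumulative from
the first beat; ``rr_intervals[i]`` is the interval ending at
``beat_times[i]`` (the first interval's opening beat precedes the record, so
its NN status depends on beat 0 alone; every later interval is NN iff both
delimiting beats are labelled N).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

NORMAL_LABEL = "N"
NON_NORMAL_LABEL = "X"

#: Default NN/RR signal-quality threshold (fraction of intervals that must
#: be normal-to-normal for a record to be analysed).
DEFAULT_NN_RR_THRESHOLD = 0.90


class Condition(str, enum.Enum):
    """Recording condition of one subject session."""

    REST = "rest"
    STRESS = "stress"


class QualityGateError(ValueError):
    """Raised when a series fails the NN/RR quality gate."""

    def __init__(self, ratio: float, threshold: float):
        self.ratio = ratio
        self.threshold = threshold
        super().__init__(
            f"NN/RR ratio {ratio:.3f} below quality threshold {threshold:.3f}"
        )


@dataclass(frozen=True)
class RRSeries:
    """Labelled beat/interval stream for one subject-condition recording."""

    subject_id: str
    condition: Condition
    beat_times: np.ndarray  # ms, cumulative, strictly increasing
    rr_intervals: np.ndarray  # ms, interval ending at each beat_time
    labels: np.ndarray  # "N" or non-N per beat

    def __post_init__(self):
        bt = np.asarray(self.beat_times, dtype=float)
        rr = np.asarray(self.rr_intervals, dtype=float)
        lab = np.asarray(self.labels, dtype=object)
        if not (len(bt) == len(rr) == len(lab)):
            raise ValueError("beat_times, rr_intervals, labels must be equal length")
        if len(rr) and np.any(rr <= 0):
            raise ValueError("all rr_intervals must be positive")
        if len(bt) > 1:
            if np.any(np.diff(bt) <= 0):
                raise ValueError("beat_times must be strictly increasing")
            if not np.allclose(np.diff(bt), rr[1:]):
                raise ValueError(
                    "beat_times[i] - beat_times[i-1] must equal rr_intervals[i]"
                )
        object.__setattr__(self, "beat_times", bt)
        object.__setattr__(self, "rr_intervals", rr)
        object.__setattr__(self, "labels", lab)

    def __len__(self) -> int:
        return len(self.rr_intervals)

    @property
    def duration_ms(self) -> float:
        """Span from the start of the first interval to the last beat."""
        if len(self) == 0:
            return 0.0
        return float(self.beat_times[-1] - self.beat_times[0] + self.rr_intervals[0])


@dataclass(frozen=True)
class NNExcerpt:
    """Quality-gated NN-interval window at a nominal time scale.

    ``onset_times`` are the ending-beat times of each interval, in ms,
    measured from the start of the parent 5-min excerpt (window membership
    downstream is decided on these times).
    """

    intervals: np.ndarray  # ms, NN only
    onset_times: np.ndarray  # ms within parent excerpt
    nominal_scale: int  # seconds: 300, 180, 120, 60 or 30
    subject_id: str = ""
    condition: Condition | None = None
    window_index: int | None = None  # None for the central placement

    def __post_init__(self):
        iv = np.asarray(self.intervals, dtype=float)
        ot = np.asarray(self.onset_times, dtype=float)
        if len(iv) != len(ot):
            raise ValueError("intervals and onset_times must be equal length")
        if len(iv) and np.any(iv <= 0):
            raise ValueError("NN intervals must be positive")
        object.__setattr__(self, "intervals", iv)
        object.__setattr__(self, "onset_times", ot)

    def __len__(self) -> int:
        return len(self.intervals)

    def with_window(self, intervals, onset_times, scale_s, index=None) -> "NNExcerpt":
        return NNExcerpt(
            intervals=intervals,
            onset_times=onset_times,
            nominal_scale=scale_s,
            subject_id=self.subject_id,
            condition=self.condition,
            window_index=index,
        )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_COLUMNS = ("time_ms", "rr_ms", "label")


def _sep_for(path: str) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".txt")) else ","


def read_rr_table(path, subject_id: str, condition: Condition | str) -> RRSeries:
    """Read a delimited beat table (time_ms, rr_ms[, label]) into an RRSeries.

    The label column is optional (defaults to normal); a header row naming the
    columns is recognised and skipped. Rows violating monotonic time or with
    non-positive intervals raise with the offending 1-based line number.
    """
    condition = Condition(condition)
    sep = _sep_for(path)
    with open(path, "r") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty RR table")
    start = 0
    first = [c.strip() for c in lines[0].split(sep)]
    if first and not _is_number(first[0]):
        start = 1  # header row
    times, rrs, labels = [], [], []
    prev_t = -np.inf
    for lineno, ln in enumerate(lines[start:], start=start + 1):
        cells = [c.strip() for c in ln.split(sep)]
        if len(cells) < 2:
            raise ValueError(f"{path}: line {lineno}: expected time_ms,rr_ms[,label]")
        try:
            t, rr = float(cells[0]), float(cells[1])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: malformed row: {ln!r}") from exc
        if rr <= 0:
            raise ValueError(f"{path}: line {lineno}: non-positive rr_ms {rr}")
        if t <= prev_t:
            raise ValueError(f"{path}: line {lineno}: time_ms not increasing")
        lab = cells[2] if len(cells) > 2 and cells[2] else NORMAL_LABEL
        times.append(t)
        rrs.append(rr)
        labels.append(NORMAL_LABEL if lab == NORMAL_LABEL else lab)
        prev_t = t
    return RRSeries(
        subject_id=subject_id,
        condition=condition,
        beat_times=np.array(times),
        rr_intervals=np.array(rrs),
        labels=np.array(labels, dtype=object),
    )


def write_rr_table(series: RRSeries, path) -> None:
    """Write an RRSeries as delimited text; round-trips with read_rr_table."""
    sep = _sep_for(path)
    df = pd.DataFrame(
        {
            "time_ms": series.beat_times,
            "rr_ms": series.rr_intervals,
            "label": series.labels,
        }
    )
    # 12 significant digits keep sub-microsecond resolution at t ~ 3e5 ms,
    # so cumulative-time consistency survives the round trip
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# NN/RR quality gate
# ---------------------------------------------------------------------------

def _nn_interval_mask(series: RRSeries) -> np.ndarray:
    """Boolean mask over intervals: True where both delimiting beats are N.

    Interval 0 has no predecessor beat in the record, so only beat 0 decides.
    """
    is_n = np.asarray([lab == NORMAL_LABEL for lab in series.labels], dtype=bool)
    if len(is_n) == 0:
        return is_n
    mask = is_n.copy()
    mask[1:] &= is_n[:-1]
    return mask


def nn_ratio(series: RRSeries) -> float:
    """Fraction of intervals that are normal-to-normal (signal quality index)."""
    if len(series) == 0:
        raise ValueError("nn_ratio undefined for an empty series")
    mask = _nn_interval_mask(series)
    return float(mask.sum() / len(mask))


def quality_gate(series: RRSeries, threshold: float = DEFAULT_NN_RR_THRESHOLD) -> bool:
    """True iff the NN/RR ratio reaches the threshold (inclusive)."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    return nn_ratio(series) >= threshold


def derive_nn(
    series: RRSeries,
    threshold: float = DEFAULT_NN_RR_THRESHOLD,
    nominal_scale: int = 300,
) -> NNExcerpt:
    """Drop non-NN intervals from a gated series (no interpolation/correction).

    Onset times are re-based so the parent excerpt starts at 0 (the opening
    edge of the first interval). Raises QualityGateError, carrying the ratio,
    if the series fails the gate.
    """
    ratio = nn_ratio(series)
    if ratio < threshold:
        raise QualityGateError(ratio, threshold)
    mask = _nn_interval_mask(series)
    t0 = series.beat_times[0] - series.rr_intervals[0]
    return NNExcerpt(
        intervals=series.rr_intervals[mask],
        onset_times=series.beat_times[mask] - t0,
        nominal_scale=nominal_scale,
        subject_id=series.subject_id,
        condition=series.condition,
    )
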