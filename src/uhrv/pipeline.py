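"""End-to-end orchestration: RR series -> quality gate -> windows -> features.

Produces the long-format feature table (subject, condition, scale_s,
window_index, feature, value, computable) that the surrogate statistics and
the classification harness consume.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .hrv_features import FEATURE_NAMES, DEFAULT_CONFIG, FeatureConfig, extract_features
from .rr_io import RRSeries, derive_nn, QualityGateError
from .segmentation import (
    SCALES_S,
    central_window,
    consecutive_windows,
    five_minute_excerpt,
)


def _rows_for(vec, subject, condition, scale_s, window_index):
    return [
        {
            "subject": subject,
            "condition": condition,
            "scale_s": scale_s,
            "window_index": window_index,
            "feature": f,
            "value": np.nan if vec.values[f] is None else vec.values[f],
            "computable": vec.computable[f],
        }
        for f in FEATURE_NAMES
    ]


def series_features(
    series: RRSeries,
    scales=SCALES_S,
    consecutive_scale: int | None = 60,
    config: FeatureConfig = DEFAULT_CONFIG,
    threshold: float = 0.90,
) -> pd.DataFrame:
    """Feature table for one recording: central windows at each scale, and
    consecutive windows at ``consecutive_scale`` (None to skip)."""
    nn = derive_nn(series, threshold=threshold)
    excerpt = five_minute_excerpt(nn)
    cond = getattr(series.condition, "value", series.condition)
    rows = []
    for scale in scales:
        win = excerpt if scale == 300 else central_window(excerpt, scale)
        rows += _rows_for(
            extract_features(win, config), series.subject_id, cond, scale, np.nan
        )
    if consecutive_scale is not None:
        for win in consecutive_windows(excerpt, consecutive_scale):
            rows += _rows_for(
                extract_features(win, config),
                series.subject_id, cond, consecutive_scale, win.window_index,
            )
    return pd.DataFrame(rows)


def cohort_features(
    cohort: list[RRSeries],
    scales=SCALES_S,
    consecutive_scale: int | None = 60,
    config: FeatureConfig = DEFAULT_CONFIG,
    threshold: float = 0.90,
    skip_failed_gate: bool = True,
) -> pd.DataFrame:
    """Concatenated feature table over a cohort of recordings.

    Recordings failing the NN/RR quality gate are skipped with a warning
    (set ``skip_failed_gate=False`` to raise instead).
    """
    frames = []
    for series in cohort:
        try:
            frames.append(
                series_features(series, scales, consecutive_scale, config, threshold)
            )
        except QualityGateError as exc:
            if not skip_failed_gate:
                raise
            warnings.warn(
                f"{series.subject_id}/{series.condition.value} excluded: {exc}"
            )
    if not frames:
        raise ValueError("no recording passed the quality gate")
    return pd.concat(frames, ignore_index=True)
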