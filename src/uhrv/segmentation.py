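"""Window extraction from a 5-min NN excerpt.

Ultra-short windows are cut from the standard 5-min (300 s) excerpt in two
ways: a single window centred in the excerpt at each nominal scale, and
consecutive non-overlapping windows tiling the excerpt at one scale (used to
check that results do not depend on where the window sits).

Windows are defined on cumulative time, not beat counts; an interval belongs
to a window when its ending beat time falls in the half-open span
``[start, end)``. Half-open membership makes consecutive windows a true
partition: each interval lands in exactly one window.
"""

from __future__ import annotations

from .rr_io import NNExcerpt

#: Nominal analysis scales, seconds (5, 3, 2, 1 min and 30 s).
SCALES_S = (300, 180, 120, 60, 30)

#: Ultra-short scales (everything below the 5-min benchmark).
ULTRA_SHORT_SCALES_S = (180, 120, 60, 30)

EXCERPT_S = 300  # benchmark excerpt length, seconds


def five_minute_excerpt(nn: NNExcerpt) -> NNExcerpt:
    """Trim an NN stream to the first 300 s (the benchmark excerpt)."""
    end_ms = EXCERPT_S * 1000.0
    keep = nn.onset_times < end_ms
    return nn.with_window(nn.intervals[keep], nn.onset_times[keep], EXCERPT_S)


def central_window(excerpt: NNExcerpt, scale_s: int) -> NNExcerpt:
    """Cut the centred window of ``scale_s`` seconds from a 5-min excerpt.

    The window is [(300 - scale)/2, (300 + scale)/2) on cumulative time;
    scale 300 is the identity.
    """
    if scale_s > EXCERPT_S:
        raise ValueError(f"scale {scale_s}s exceeds the {EXCERPT_S}s excerpt")
    if excerpt.nominal_scale != EXCERPT_S:
        raise ValueError("central_window expects a 300-s parent excerpt")
    start_ms = (EXCERPT_S - scale_s) / 2 * 1000.0
    end_ms = (EXCERPT_S + scale_s) / 2 * 1000.0
    keep = (excerpt.onset_times >= start_ms) & (excerpt.onset_times < end_ms)
    return excerpt.with_window(
        excerpt.intervals[keep], excerpt.onset_times[keep], scale_s
    )


def consecutive_windows(excerpt: NNExcerpt, scale_s: int) -> list[NNExcerpt]:
    """Tile the 5-min excerpt with disjoint ``scale_s``-second windows.

    Windows are [k*scale, (k+1)*scale) for k = 0 .. floor(300/scale) - 1; any
    trailing remainder is discarded.
    """
    if scale_s > EXCERPT_S:
        raise ValueError(f"scale {scale_s}s exceeds the {EXCERPT_S}s excerpt")
    if excerpt.nominal_scale != EXCERPT_S:
        raise ValueError("consecutive_windows expects a 300-s parent excerpt")
    n_windows = EXCERPT_S // scale_s
    out = []
    for k in range(n_windows):
        start_ms = k * scale_s * 1000.0
        end_ms = (k + 1) * scale_s * 1000.0
        keep = (excerpt.onset_times >= start_ms) & (excerpt.onset_times < end_ms)
        out.append(
            excerpt.with_window(
                excerpt.intervals[keep], excerpt.onset_times[keep], scale_s, index=k
            )
        )
    return out
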