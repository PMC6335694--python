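"""The 23-feature HRV catalogue: time, AR-spectral and non-linear domains.

Features are computed from an NN-interval excerpt at one nominal time scale
(300, 180, 120, 60 or 30 s). Not every feature is defined at every scale:
spectral estimates need recordings at least ten times the wavelength of the
band's lower frequency edge (so LF, LF/HF and total power need >= 120 s and HF
needs >= 60 s), approximate entropy is unreliable below 180 s, and most
non-linear statistics run out of samples at 30 s. ``computability_mask``
encodes that pattern; masked features are reported as explicit nulls with a
False computability flag, never as silent zeros.

Catalogue (units):
  time domain     — MeanNN, StdNN, RMSSD (ms); MeanHR, StdHR (bpm);
                    NN50 (count); pNN50 (%)
  frequency       — LF (0.04-0.15 Hz), HF (0.15-0.4 Hz), TotPow (0-0.4 Hz)
                    in ms^2 from an autoregressive (Burg) spectrum of the
                    evenly resampled tachogram; LF/HF ratio
  non-linear      — SD1, SD2 (ms, Poincare plot axes); ApEn, SampEn (nats);
                    D2 (correlation dimension); dfa1, dfa2 (DFA scaling
                    exponents); RPlmean, RPlmax (beats), REC, RPadet (%),
                    ShanEn (recurrence-plot diagonal-line statistics)

Variance convention is population (divide by N) throughout, which makes the
identity SD1 = RMSSD / sqrt(2) exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import CubicSpline
from scipy.signal import detrend as _linear_detrend
from statsmodels.regression.linear_model import burg as _burg

from .rr_io import NNExcerpt

# canonical feature order
FEATURE_NAMES = (
    "MeanNN", "StdNN", "MeanHR", "StdHR", "RMSSD", "NN50", "pNN50",
    "LF", "HF", "LF/HF", "TotPow",
    "SD1", "SD2", "ApEn", "SampEn", "D2", "dfa1", "dfa2",
    "RPlmean", "RPlmax", "REC", "RPadet", "ShanEn",
)

TIME_DOMAIN = ("MeanNN", "StdNN", "MeanHR", "StdHR", "RMSSD", "NN50", "pNN50")
FREQ_DOMAIN = ("LF", "HF", "LF/HF", "TotPow")

VLF_LO_HZ, LF_LO_HZ, LF_HI_HZ, HF_HI_HZ = 0.0, 0.04, 0.15, 0.40


@dataclass
class FeatureConfig:
    """Tunable parameters of the extractor (defaults are the package's)."""

    ar_order: int = 16
    resample_hz: float = 4.0
    entropy_m: int = 2
    entropy_r_frac: float = 0.2  # tolerance as fraction of SD
    dfa_short_range: tuple[int, int] = (4, 16)
    dfa_long_range: tuple[int, int] = (16, 64)
    rqa_m: int = 10
    rqa_tau: int = 1
    rqa_lmin: int = 2
    d2_m: int = 10
    shanen_base: str = "nats"  # or "bits"
    ddof: int = 0  # population variance convention


DEFAULT_CONFIG = FeatureConfig()


@dataclass
class FeatureVector:
    """The 23 named HRV features plus a per-feature computability mask."""

    values: dict[str, float | None]
    computable: dict[str, bool]
    nominal_scale: int
    subject_id: str = ""
    condition: str | None = None
    window_index: int | None = None

    def __post_init__(self):
        missing = set(FEATURE_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"feature vector missing {sorted(missing)}")

    def __getitem__(self, name: str) -> float | None:
        return self.values[name]

    def n_computable(self) -> int:
        return sum(self.computable[f] for f in FEATURE_NAMES)


# ---------------------------------------------------------------------------
# time domain
# ---------------------------------------------------------------------------

def time_features(x: NNExcerpt, config: FeatureConfig = DEFAULT_CONFIG) -> dict:
    """Time-domain features; all NaN-flagged if fewer than 2 intervals."""
    nn = np.asarray(x.intervals, dtype=float)
    if len(nn) < 2:
        return {f: None for f in TIME_DOMAIN}
    hr = 60000.0 / nn  # instantaneous heart rate, bpm
    d = np.diff(nn)
    nn50 = int(np.sum(np.abs(d) > 50.0))
    return {
        "MeanNN": float(np.mean(nn)),
        "StdNN": float(np.std(nn, ddof=config.ddof)),
        "MeanHR": float(np.mean(hr)),
        "StdHR": float(np.std(hr, ddof=config.ddof)),
        "RMSSD": float(np.sqrt(np.mean(d**2))),
        "NN50": float(nn50),
        "pNN50": float(100.0 * nn50 / (len(nn) - 1)),
    }


# ---------------------------------------------------------------------------
# frequency domain (autoregressive spectrum)
# ---------------------------------------------------------------------------

@dataclass
class SpectralEstimate:
    """AR power spectral density of the evenly resampled tachogram."""

    freqs: np.ndarray  # Hz
    psd: np.ndarray  # one-sided, ms^2/Hz
    model_order: int
    sampling_rate_hz: float


def resample_tachogram(
    x: NNExcerpt, fs: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline interpolation of NN vs time onto an even grid at ``fs``."""
    t = np.asarray(x.onset_times, dtype=float) / 1000.0  # s
    nn = np.asarray(x.intervals, dtype=float)
    if len(nn) < 4:
        raise ValueError("need at least 4 NN intervals for cubic resampling")
    spline = CubicSpline(t, nn)
    n = int(np.floor((t[-1] - t[0]) * fs)) + 1
    tg = t[0] + np.arange(n) / fs
    return tg, spline(tg)


def ar_psd(
    x: NNExcerpt,
    order: int | None = None,
    fs: float | None = None,
    config: FeatureConfig = DEFAULT_CONFIG,
    n_freq: int = 4096,
) -> SpectralEstimate | None:
    """Burg autoregressive PSD of the detrended, evenly resampled tachogram.

    Returns None (non-computable) when the excerpt is too short to resample
    or to support the model order. The one-sided PSD integrates (trapezoid)
    to approximately the variance of the detrended resampled signal.
    """
    order = config.ar_order if order is None else order
    fs = config.resample_hz if fs is None else fs
    try:
        _, sig = resample_tachogram(x, fs)
    except ValueError:
        return None
    if len(sig) < order + 1:
        return None
    sig = _linear_detrend(sig, type="linear")
    if np.allclose(sig, 0.0):
        # constant tachogram: spectrum is identically zero
        freqs = np.linspace(0.0, fs / 2, n_freq)
        return SpectralEstimate(freqs, np.zeros(n_freq), order, fs)
    ar_coeffs, sigma2 = _burg(sig, order=order, demean=True)
    freqs = np.linspace(0.0, fs / 2, n_freq)
    z = np.exp(-2j * np.pi * freqs[:, None] / fs * np.arange(1, order + 1))
    denom = np.abs(1.0 - z @ ar_coeffs) ** 2
    psd = 2.0 * sigma2 / fs / denom  # one-sided
    # The theoretical integral of the AR spectrum is the signal variance, but
    # near-unit-circle poles make peaks narrower than any finite grid; rescale
    # the discretised spectrum so its trapezoid integral restores the total.
    integral = float(np.trapezoid(psd, freqs))
    if integral > 0:
        psd = psd * (float(np.var(sig)) / integral)
    return SpectralEstimate(freqs, psd, order, fs)


def _band_power(spec: SpectralEstimate, lo: float, hi: float) -> float:
    m = (spec.freqs >= lo) & (spec.freqs <= hi)
    return float(np.trapezoid(spec.psd[m], spec.freqs[m]))


def band_powers(spec: SpectralEstimate | None, excerpt_length_s: float) -> dict:
    """LF/HF/TotPow band powers with the excerpt-length computability rules.

    Spectral estimates need records at least 10 wavelengths of the band's
    lower edge: LF (and the ratio and total power) require >= 120 s, HF
    requires >= 60 s. Masked entries are None, never zero.
    """
    out: dict[str, float | None] = {f: None for f in FREQ_DOMAIN}
    lf_ok = excerpt_length_s >= 120
    hf_ok = excerpt_length_s >= 60
    if spec is None:
        return out
    if hf_ok:
        out["HF"] = _band_power(spec, LF_HI_HZ, HF_HI_HZ)
    if lf_ok:
        out["LF"] = _band_power(spec, LF_LO_HZ, LF_HI_HZ)
        out["TotPow"] = _band_power(spec, VLF_LO_HZ, HF_HI_HZ)
        if out["HF"] is not None and out["HF"] > 0:
            out["LF/HF"] = out["LF"] / out["HF"]
    return out


# ---------------------------------------------------------------------------
# non-linear: Poincare plot
# ---------------------------------------------------------------------------

def poincare(x: NNExcerpt, config: FeatureConfig = DEFAULT_CONFIG):
    """Poincare-plot axes: SD1 (short-term) and SD2 (long-term), in ms.

    SD1^2 = mean(successive differences squared)/2 (the dispersion of the
    Poincare cloud about the identity line, whose centre is taken at zero
    difference), SD2^2 = 2 var(NN) - SD1^2 with the population variance
    convention shared with StdNN, so SD1 = RMSSD/sqrt(2) exactly.
    """
    nn = np.asarray(x.intervals, dtype=float)
    if len(nn) < 3:
        return None, None
    d = np.diff(nn)
    vnn = np.var(nn, ddof=config.ddof)
    sd1_sq = 0.5 * float(np.mean(d**2))
    sd2_sq = max(2.0 * vnn - sd1_sq, 0.0)
    return float(np.sqrt(sd1_sq)), float(np.sqrt(sd2_sq))


# ---------------------------------------------------------------------------
# non-linear: entropies
# ---------------------------------------------------------------------------

def _chebyshev_template_counts(x: np.ndarray, m: int, r: float, n_templates: int):
    """Pair-count of templates of length m within Chebyshev distance r.

    Counts unordered pairs i < j over the first ``n_templates`` templates.
    """
    tpl = sliding_window_view(x, m)[:n_templates]
    # pairwise Chebyshev distances; n <= ~600 so the dense matrix is fine
    d = np.max(np.abs(tpl[:, None, :] - tpl[None, :, :]), axis=-1)
    iu = np.triu_indices(n_templates, k=1)
    return int(np.sum(d[iu] <= r))


def sample_entropy(
    x: NNExcerpt | np.ndarray,
    m: int | None = None,
    r_frac: float | None = None,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> float | None:
    """Sample entropy: -ln(A/B), self-matches excluded (Richman-Moorman).

    B counts m-template pairs and A counts (m+1)-template pairs within
    tolerance r = r_frac * SD(x) (Chebyshev distance), both over the first
    N - m templates. None when either count is zero.
    """
    m = config.entropy_m if m is None else m
    r_frac = config.entropy_r_frac if r_frac is None else r_frac
    xa = np.asarray(getattr(x, "intervals", x), dtype=float)
    n = len(xa)
    if n < m + 2:
        return None
    r = r_frac * np.std(xa, ddof=config.ddof)
    b = _chebyshev_template_counts(xa, m, r, n - m)
    a = _chebyshev_template_counts(xa, m + 1, r, n - m)
    if a == 0 or b == 0:
        return None
    return float(-np.log(a / b))


def approximate_entropy(
    x: NNExcerpt | np.ndarray,
    m: int | None = None,
    r_frac: float | None = None,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> float | None:
    """Approximate entropy: Phi_m - Phi_{m+1}, self-matches included."""
    m = config.entropy_m if m is None else m
    r_frac = config.entropy_r_frac if r_frac is None else r_frac
    xa = np.asarray(getattr(x, "intervals", x), dtype=float)
    n = len(xa)
    if n < m + 2:
        return None
    r = r_frac * np.std(xa, ddof=config.ddof)

    def phi(mm: int) -> float:
        tpl = sliding_window_view(xa, mm)
        d = np.max(np.abs(tpl[:, None, :] - tpl[None, :, :]), axis=-1)
        c = np.mean(d <= r, axis=1)  # includes the self-match
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


# ---------------------------------------------------------------------------
# non-linear: detrended fluctuation analysis
# ---------------------------------------------------------------------------

def _dfa_fluctuation(y: np.ndarray, box: int) -> float | None:
    """RMS residual of per-box linear detrending of the integrated series."""
    n_boxes = len(y) // box
    if n_boxes < 1:
        return None
    t = np.arange(box, dtype=float)
    resid_sq = 0.0
    for b in range(n_boxes):
        seg = y[b * box:(b + 1) * box]
        coef = np.polyfit(t, seg, 1)
        resid_sq += float(np.sum((seg - np.polyval(coef, t)) ** 2))
    return math.sqrt(resid_sq / (n_boxes * box))


def dfa(
    x: NNExcerpt | np.ndarray, config: FeatureConfig = DEFAULT_CONFIG
):
    """DFA scaling exponents alpha1 (boxes 4-16) and alpha2 (boxes 16-64).

    The interval series is mean-centred and integrated; each exponent is the
    least-squares slope of log F(n) against log n over its box-size range.
    An exponent is None when fewer than two box sizes fit in the series.
    """
    xa = np.asarray(getattr(x, "intervals", x), dtype=float)
    if len(xa) < 2 * config.dfa_short_range[0]:
        return None, None
    y = np.cumsum(xa - np.mean(xa))

    def alpha(lo: int, hi: int) -> float | None:
        sizes, fs_ = [], []
        for box in range(lo, hi + 1):
            if box > len(y):
                break
            f = _dfa_fluctuation(y, box)
            if f is not None and f > 0:
                sizes.append(box)
                fs_.append(f)
        if len(sizes) < 2:
            return None
        slope = np.polyfit(np.log10(sizes), np.log10(fs_), 1)[0]
        return float(slope)

    return (
        alpha(*config.dfa_short_range),
        alpha(*config.dfa_long_range),
    )


# ---------------------------------------------------------------------------
# non-linear: correlation dimension (Grassberger-Procaccia)
# ---------------------------------------------------------------------------

def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n = len(x) - (m - 1) * tau
    if n < 2:
        return np.empty((0, m))
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def correlation_dimension(
    x: NNExcerpt | np.ndarray,
    m: int | None = None,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> float | None:
    """Correlation dimension D2 at embedding dimension m, delay 1.

    Slope of log C(r) vs log r over an automatically selected scaling region
    (grid points where the correlation sum C(r) lies between 1% and 20% of
    pairs, widened to 50% when too narrow). None when no scaling region with
    at least four grid points exists.
    """
    m = config.d2_m if m is None else m
    xa = np.asarray(getattr(x, "intervals", x), dtype=float)
    emb = _embed(xa, m, 1)
    if len(emb) < 20:
        return None
    diffs = emb[:, None, :] - emb[None, :, :]
    dist = np.sqrt(np.sum(diffs**2, axis=-1))
    iu = np.triu_indices(len(emb), k=1)
    pd = dist[iu]
    pd_pos = pd[pd > 0]
    if len(pd_pos) < 10:
        return None  # degenerate (e.g. constant series)
    r_grid = np.logspace(
        np.log10(np.quantile(pd_pos, 0.001)), np.log10(pd_pos.max()), 60
    )
    c = np.searchsorted(np.sort(pd), r_grid, side="right") / len(pd)
    for lo, hi in ((0.01, 0.20), (0.01, 0.50)):
        sel = (c >= lo) & (c <= hi) & (r_grid > 0)
        if np.sum(sel) >= 4:
            slope = np.polyfit(np.log10(r_grid[sel]), np.log10(c[sel]), 1)[0]
            return float(slope)
    return None


# ---------------------------------------------------------------------------
# non-linear: recurrence quantification analysis
# ---------------------------------------------------------------------------

def _diagonal_line_lengths(rec: np.ndarray, lmin: int) -> list[int]:
    """Lengths (>= lmin) of diagonal lines in the upper triangle of R."""
    n = rec.shape[0]
    lengths = []
    for k in range(1, n):
        diag = np.diagonal(rec, offset=k)
        run = 0
        for v in diag:
            if v:
                run += 1
            else:
                if run >= lmin:
                    lengths.append(run)
                run = 0
        if run >= lmin:
            lengths.append(run)
    return lengths


def rqa(
    x: NNExcerpt | np.ndarray,
    m: int | None = None,
    tau: int | None = None,
    lmin: int | None = None,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> dict:
    """Recurrence quantification: RPlmean, RPlmax, REC, RPadet, ShanEn.

    Recurrence matrix R(i,j) = [||v_i - v_j|| <= r] on m-dimensional delay
    embeddings (Euclidean norm, r = sqrt(m) * SD(x)). The line of identity is
    excluded. REC is the % of recurrent points; diagonal lines of length >=
    lmin give RPlmean (mean length, beats), RPlmax (max length), RPadet
    (determinism, % of recurrent points on such lines) and ShanEn (Shannon
    entropy of the line-length distribution, nats by default).
    """
    m = config.rqa_m if m is None else m
    tau = config.rqa_tau if tau is None else tau
    lmin = config.rqa_lmin if lmin is None else lmin
    xa = np.asarray(getattr(x, "intervals", x), dtype=float)
    out = {k: None for k in ("RPlmean", "RPlmax", "REC", "RPadet", "ShanEn")}
    emb = _embed(xa, m, tau)
    n = len(emb)
    if n < lmin + 1:
        return out
    r = math.sqrt(m) * np.std(xa, ddof=config.ddof)
    diffs = emb[:, None, :] - emb[None, :, :]
    rec = np.sqrt(np.sum(diffs**2, axis=-1)) <= r
    iu = np.triu_indices(n, k=1)
    n_rec_upper = int(np.sum(rec[iu]))
    out["REC"] = float(100.0 * n_rec_upper / len(iu[0]))
    if n_rec_upper == 0:
        out["RPadet"] = 0.0
        return out
    lengths = _diagonal_line_lengths(rec, lmin)
    if not lengths:
        out["RPadet"] = 0.0
        return out
    lengths = np.asarray(lengths)
    out["RPlmean"] = float(np.mean(lengths))
    out["RPlmax"] = float(np.max(lengths))
    out["RPadet"] = float(100.0 * np.sum(lengths) / n_rec_upper)
    _, counts = np.unique(lengths, return_counts=True)
    p = counts / counts.sum()
    shanen = float(-np.sum(p * np.log(p)))
    if config.shanen_base == "bits":
        shanen /= math.log(2)
    out["ShanEn"] = shanen
    return out


# ---------------------------------------------------------------------------
# computability mask and dispatch
# ---------------------------------------------------------------------------

_MASKED_AT: dict[int, frozenset] = {
    300: frozenset(),
    180: frozenset(),
    120: frozenset({"ApEn"}),
    60: frozenset({"LF", "LF/HF", "TotPow", "ApEn"}),
    30: frozenset(set(FEATURE_NAMES) - set(TIME_DOMAIN) - {"SD1", "SD2"}),
}


def computability_mask(nominal_scale: int) -> dict[str, bool]:
    """Which of the 23 features are defined at a nominal scale (seconds).

    300/180 s: all 23; 120 s: all but ApEn; 60 s: HF and the non-linear set
    but not LF/LF/HF/TotPow/ApEn; 30 s: the 7 time-domain features plus
    SD1 and SD2 only.
    """
    if nominal_scale not in _MASKED_AT:
        raise ValueError(f"unknown nominal scale {nominal_scale}s")
    masked = _MASKED_AT[nominal_scale]
    return {f: f not in masked for f in FEATURE_NAMES}


def extract_features(
    x: NNExcerpt, config: FeatureConfig = DEFAULT_CONFIG
) -> FeatureVector:
    """Compute the full 23-feature vector for one excerpt.

    Scale-masked features are skipped; features that fail numerically on a
    particular excerpt (e.g. no D2 scaling region) come back flagged
    non-computable rather than aborting the vector.
    """
    mask = computability_mask(x.nominal_scale)
    values: dict[str, float | None] = {f: None for f in FEATURE_NAMES}

    values.update(time_features(x, config))

    if any(mask[f] for f in FREQ_DOMAIN):
        spec = ar_psd(x, config=config)
        bp = band_powers(spec, x.nominal_scale)
        for f in FREQ_DOMAIN:
            if mask[f]:
                values[f] = bp[f]

    sd1, sd2 = poincare(x, config)
    values["SD1"], values["SD2"] = sd1, sd2

    if mask["SampEn"]:
        values["SampEn"] = sample_entropy(x, config=config)
    if mask["ApEn"]:
        values["ApEn"] = approximate_entropy(x, config=config)
    if mask["dfa1"] or mask["dfa2"]:
        a1, a2 = dfa(x, config)
        if mask["dfa1"]:
            values["dfa1"] = a1
        if mask["dfa2"]:
            values["dfa2"] = a2
    if mask["D2"]:
        values["D2"] = correlation_dimension(x, config=config)
    if any(mask[f] for f in ("RPlmean", "RPlmax", "REC", "RPadet", "ShanEn")):
        rq = rqa(x, config=config)
        for f, v in rq.items():
            if mask[f]:
                values[f] = v

    # drop values the scale mask forbids (defensive; they were never computed)
    for f in FEATURE_NAMES:
        if not mask[f]:
            values[f] = None
    computable = {f: (mask[f] and values[f] is not None) for f in FEATURE_NAMES}
    return FeatureVector(
        values=values,
        computable=computable,
        nominal_scale=x.nominal_scale,
        subject_id=x.subject_id,
        condition=getattr(x.condition, "value", x.condition),
        window_index=x.window_index,
    )
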