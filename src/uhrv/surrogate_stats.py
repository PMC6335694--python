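"""Surrogate validation of ultra-short HRV features against the 5-min benchmark.

A shortened measurement is accepted as a surrogate of the standard 5-min one
only when two independent lines of evidence agree at every retained scale:

* trend consistency (inter-group): the stress-vs-rest change is significant
  (paired Wilcoxon signed-rank, two-sided p < 0.05) with the same direction
  as at 5 min, at every scale;
* correlation (intra-group): the ultra-short feature tracks its 5-min
  equivalent across subjects, Spearman rho > 0.7 with p_rho < 0.05, in both
  rest and stress phases.

Bland-Altman bias and 95% limits of agreement quantify absolute agreement but
are advisory, never part of the pass/fail gate. Scales where too few features
behave coherently with the benchmark (fewer than ``min_pass``) are dropped
before the final per-feature verdicts.

No multiple-testing correction is applied by default; ``adjust="bh"`` applies
Benjamini-Hochberg within a trend table for users who want it.
"""

from __future__ import annotations

import enum
import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_ALPHA = 0.05
DEFAULT_RHO_MIN = 0.7
DEFAULT_MIN_PASS = 3
EXACT_WILCOXON_MAX_N = 15


class TrendCode(str, enum.Enum):
    """Arrow notation for the stress-vs-rest median trend."""

    SIG_DOWN = "SIG_DOWN"  # significantly lower under stress
    SIG_UP = "SIG_UP"
    NS_DOWN = "NS_DOWN"
    NS_UP = "NS_UP"
    NA = "NA"  # feature not computable at the scale

    @property
    def glyph(self) -> str:
        return {
            "SIG_DOWN": "↓↓", "SIG_UP": "↑↑",
            "NS_DOWN": "↓", "NS_UP": "↑", "NA": "–",
        }[self.value]

    @property
    def significant(self) -> bool:
        return self in (TrendCode.SIG_DOWN, TrendCode.SIG_UP)

    @property
    def direction(self) -> str | None:
        if self is TrendCode.NA:
            return None
        return "down" if "DOWN" in self.value else "up"


@dataclass(frozen=True)
class AgreementSummary:
    """Bland-Altman comparison of paired 5-min vs ultra-short measurements."""

    feature: str
    scale_s: int
    phase: str
    bias: float  # median of (5-min minus ultra-short) differences
    loa_low: float  # mean(d) - 1.96 SD(d)
    loa_high: float  # mean(d) + 1.96 SD(d)
    mean_diff: float


@dataclass
class SurrogateVerdict:
    """Gate outcome for one feature over the retained scales."""

    feature: str
    retained_scales: tuple[int, ...]
    passed: bool
    undetermined: bool = False
    reasons: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def _signed_ranks(d: np.ndarray):
    d = d[d != 0.0]
    ranks = sps.rankdata(np.abs(d))  # average ranks for ties
    return d, ranks


def wilcoxon_signed_rank(x, y) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value for x vs y.

    Zero differences are dropped. With n <= 15 remaining pairs the exact null
    distribution is enumerated over all 2^n sign assignments (valid with tied
    ranks); above that a normal approximation with continuity and tie
    corrections is used. All differences zero gives p = 1 with a warning.
    """
    d = np.asarray(y, dtype=float) - np.asarray(x, dtype=float)
    d, ranks = _signed_ranks(d)
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 1.0
    w_plus = float(np.sum(ranks[d > 0]))
    if n <= EXACT_WILCOXON_MAX_N:
        # enumerate W+ over every sign assignment
        signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        w_all = signs @ ranks
        ge = np.mean(w_all >= w_plus)
        le = np.mean(w_all <= w_plus)
        return float(min(1.0, 2.0 * min(ge, le)))
    mu = n * (n + 1) / 4.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        tie_counts**3 - tie_counts
    ) / 48.0
    if var <= 0:
        return 1.0
    cc = 0.5 * np.sign(w_plus - mu)  # continuity correction
    z = (w_plus - mu - cc) / np.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def encode_trend(
    p: float | None,
    median_rest: float | None,
    median_stress: float | None,
    alpha: float = DEFAULT_ALPHA,
) -> TrendCode:
    """Map a p-value and the median change to the arrow code.

    A decrease means the stress median is below the rest median; exact ties
    are encoded as a (non-significant) increase by convention. None inputs
    (masked feature) give NA.
    """
    if p is None or median_rest is None or median_stress is None:
        return TrendCode.NA
    if not (np.isfinite(median_rest) and np.isfinite(median_stress)):
        return TrendCode.NA
    down = median_stress < median_rest
    if p < alpha:
        return TrendCode.SIG_DOWN if down else TrendCode.SIG_UP
    return TrendCode.NS_DOWN if down else TrendCode.NS_UP


def spearman(x, y) -> tuple[float | None, float | None]:
    """Spearman rank correlation (average ranks for ties) and its p-value.

    Returns (None, None) when either vector has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        return None, None
    rho, p = sps.spearmanr(x, y)
    if not np.isfinite(rho):
        return None, None
    return float(rho), float(p)


def bland_altman(
    short_vals, ultra_vals, feature: str = "", scale_s: int = 0, phase: str = ""
) -> AgreementSummary:
    """Bland-Altman agreement of ultra-short vs 5-min paired measurements.

    Differences are 5-min minus ultra-short. The bias is the median
    difference; the 95% limits of agreement are mean(d) +/- 1.96 SD(d).
    """
    s = np.asarray(short_vals, dtype=float)
    u = np.asarray(ultra_vals, dtype=float)
    if len(s) != len(u) or len(s) < 3:
        raise ValueError("need >= 3 paired values")
    d = s - u
    sd = float(np.std(d, ddof=1))
    md = float(np.mean(d))
    return AgreementSummary(
        feature=feature, scale_s=scale_s, phase=phase,
        bias=float(np.median(d)),
        loa_low=md - 1.96 * sd, loa_high=md + 1.96 * sd, mean_diff=md,
    )


# ---------------------------------------------------------------------------
# tables from cohort feature data
# ---------------------------------------------------------------------------

def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * n / (rank_idx + 1))
        adj[i] = running
    return adj


def trend_table(
    features: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-feature, per-scale stress-vs-rest trend codes from a long table.

    ``features`` is long-format with columns (subject, condition, scale_s,
    feature, value); non-computable entries are NaN. Returns a table with
    columns (feature, scale_s, p_value, median_rest, median_stress, code).
    """
    rows = []
    for (feat, scale), grp in features.groupby(["feature", "scale_s"]):
        wide = grp.pivot_table(
            index="subject", columns="condition", values="value", aggfunc="first"
        )
        if (
            "rest" not in wide or "stress" not in wide
            or wide[["rest", "stress"]].dropna().empty
        ):
            rows.append((feat, scale, np.nan, np.nan, np.nan))
            continue
        paired = wide[["rest", "stress"]].dropna()
        p = wilcoxon_signed_rank(paired["rest"].values, paired["stress"].values)
        rows.append(
            (feat, scale, p,
             float(paired["rest"].median()), float(paired["stress"].median()))
        )
    out = pd.DataFrame(
        rows, columns=["feature", "scale_s", "p_value", "median_rest", "median_stress"]
    )
    if adjust == "bh":
        ok = out["p_value"].notna()
        out.loc[ok, "p_value"] = _bh_adjust(out.loc[ok, "p_value"].values)
    out["code"] = [
        encode_trend(
            None if np.isnan(r.p_value) else r.p_value,
            r.median_rest, r.median_stress, alpha,
        ).value
        for r in out.itertuples()
    ]
    return out


def correlation_table(features: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho of each ultra-short feature against its 5-min equivalent.

    One row per (feature, ultra-short scale, phase); entries where either
    vector is unavailable or degenerate carry NaN.
    """
    rows = []
    bench = features[features["scale_s"] == 300]
    for (feat, scale, phase), grp in features[features["scale_s"] != 300].groupby(
        ["feature", "scale_s", "condition"]
    ):
        b = bench[(bench["feature"] == feat) & (bench["condition"] == phase)]
        merged = pd.merge(
            grp[["subject", "value"]], b[["subject", "value"]],
            on="subject", suffixes=("_ultra", "_short"),
        ).dropna()
        if len(merged) < 5:
            rows.append((feat, scale, phase, np.nan, np.nan))
            continue
        rho, p = spearman(merged["value_short"], merged["value_ultra"])
        rows.append(
            (feat, scale, phase,
             np.nan if rho is None else rho, np.nan if p is None else p)
        )
    return pd.DataFrame(rows, columns=["feature", "scale_s", "phase", "rho", "p_rho"])


# ---------------------------------------------------------------------------
# the gate
# ---------------------------------------------------------------------------

def _codes_by_scale(trends: pd.DataFrame, feature: str) -> dict[int, TrendCode]:
    sub = trends[trends["feature"] == feature]
    return {
        int(r.scale_s): TrendCode(r.code) for r in sub.itertuples()
    }


def surrogate_gate(
    trends: pd.DataFrame,
    correlations: pd.DataFrame,
    retained_scales,
    rho_min: float = DEFAULT_RHO_MIN,
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, SurrogateVerdict]:
    """Per-feature surrogate verdicts over the retained ultra-short scales.

    A feature passes iff (a) its trend is significant at the 5-min benchmark
    and significant with the same direction at every retained scale, and
    (b) rho > rho_min with p_rho < alpha at every retained scale in both rest
    and stress phases. Missing table entries make the verdict undetermined.
    """
    retained = tuple(sorted(set(int(s) for s in retained_scales), reverse=True))
    verdicts: dict[str, SurrogateVerdict] = {}
    for feature in trends["feature"].unique():
        codes = _codes_by_scale(trends, feature)
        v = SurrogateVerdict(feature=feature, retained_scales=retained, passed=True)
        bench = codes.get(300)
        if bench is None:
            v.undetermined = True
            v.reasons.append("no benchmark (300 s) trend entry")
            v.passed = False
            verdicts[feature] = v
            continue
        if not bench.significant:
            v.passed = False
            v.reasons.append("trend not significant at 300 s benchmark")
        for scale in retained:
            code = codes.get(scale)
            if code is None:
                v.undetermined = True
                v.passed = False
                v.reasons.append(f"missing trend entry at {scale} s")
                continue
            if code is TrendCode.NA:
                v.passed = False
                v.reasons.append(f"not computable at {scale} s")
                continue
            if not (code.significant and code.direction == bench.direction):
                v.passed = False
                v.reasons.append(f"trend inconsistent with benchmark at {scale} s")
            for phase in ("rest", "stress"):
                row = correlations[
                    (correlations["feature"] == feature)
                    & (correlations["scale_s"] == scale)
                    & (correlations["phase"] == phase)
                ]
                if row.empty or not np.isfinite(row["rho"].iloc[0]):
                    v.undetermined = True
                    v.passed = False
                    v.reasons.append(f"missing correlation at {scale} s ({phase})")
                    continue
                rho, p_rho = float(row["rho"].iloc[0]), float(row["p_rho"].iloc[0])
                if not (rho > rho_min and p_rho < alpha):
                    v.passed = False
                    v.reasons.append(
                        f"rho {rho:.3f} (p {p_rho:.3g}) fails at {scale} s ({phase})"
                    )
        verdicts[feature] = v
    return verdicts


def per_scale_pass_counts(
    trends: pd.DataFrame,
    correlations: pd.DataFrame,
    candidate_scales=(180, 120, 60, 30),
    rho_min: float = DEFAULT_RHO_MIN,
    alpha: float = DEFAULT_ALPHA,
) -> dict[int, int]:
    """How many features meet both gate criteria at each scale in isolation."""
    counts = {}
    for scale in candidate_scales:
        verdicts = surrogate_gate(
            trends, correlations, [scale], rho_min=rho_min, alpha=alpha
        )
        counts[int(scale)] = sum(v.passed for v in verdicts.values())
    return counts


def scale_retention(
    pass_counts: dict[int, int], min_pass: int = DEFAULT_MIN_PASS
) -> set[int]:
    """Retain the scales where at least ``min_pass`` features pass the gate."""
    retained = {s for s, c in pass_counts.items() if c >= min_pass}
    if not retained:
        warnings.warn("no scale reaches the retention threshold; empty set")
    return retained


def run_surrogate_analysis(
    trends: pd.DataFrame,
    correlations: pd.DataFrame,
    candidate_scales=(180, 120, 60, 30),
    rho_min: float = DEFAULT_RHO_MIN,
    alpha: float = DEFAULT_ALPHA,
    min_pass: int = DEFAULT_MIN_PASS,
):
    """Scale retention followed by the gate; returns (retained, verdicts)."""
    counts = per_scale_pass_counts(
        trends, correlations, candidate_scales, rho_min, alpha
    )
    retained = scale_retention(counts, min_pass)
    verdicts = surrogate_gate(trends, correlations, retained, rho_min, alpha)
    return retained, verdicts


def surrogate_features(verdicts: dict[str, SurrogateVerdict]) -> list[str]:
    """Names of the features that passed the gate, in catalogue order."""
    from .hrv_features import FEATURE_NAMES

    passed = {f for f, v in verdicts.items() if v.passed}
    return [f for f in FEATURE_NAMES if f in passed]


# ---------------------------------------------------------------------------
# transcribed reference tables
# ---------------------------------------------------------------------------

def _load_data_csv(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("uhrv.data").joinpath(name)
    with ref.open("r") as fh:
        # keep the literal "NA" trend code out of pandas' default NaN set
        return pd.read_csv(fh, comment="#", keep_default_na=False, na_values=[""])


def load_reference_trends() -> pd.DataFrame:
    """Published per-scale trend codes (feature, scale_s, code)."""
    return _load_data_csv("table1_trends.csv")


def load_reference_correlations() -> pd.DataFrame:
    """Published ultra-short vs 5-min Spearman coefficients."""
    return _load_data_csv("table2_rhos.csv")


def trend_table_markdown(trends: pd.DataFrame) -> str:
    """Arrow-glyph rendering of a trend table (features x scales)."""
    scales = sorted(trends["scale_s"].unique(), reverse=True)
    piv = trends.pivot_table(
        index="feature", columns="scale_s", values="code", aggfunc="first"
    )
    lines = ["| feature | " + " | ".join(f"{s} s" for s in scales) + " |"]
    lines.append("|" + "---|" * (len(scales) + 1))
    for feat, row in piv.iterrows():
        glyphs = [TrendCode(row[s]).glyph if pd.notna(row.get(s)) else "–"
                  for s in scales]
        lines.append(f"| {feat} | " + " | ".join(glyphs) + " |")
    return "\n".join(lines)
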