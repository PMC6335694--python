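"""Synthetic paired rest/stress RR-interval cohorts with known structure.

The tachogram model is sinusoid-plus-noise: each RR interval is a subject
mean plus a low-frequency (0.10 Hz) and a high-frequency (0.25 Hz,
respiratory-band) oscillation plus white noise, evaluated at the cumulative
beat time. This gives direct control over the quantities the pipeline
measures — MeanNN is the programmed mean, the HF band power of a pure tone of
amplitude A is A^2/2 ms^2, StdNN follows from the amplitudes and noise — while
remaining far simpler than a full cardiovascular model.

The default condition contrast emulates mental stress as observed in young
healthy adults: shorter mean NN (higher heart rate), reduced overall and
respiratory-band variability, and — because instantaneous heart rate
60000/NN amplifies variability at short NN — a higher heart-rate standard
deviation despite the lower StdNN.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .rr_io import Condition, NORMAL_LABEL, NON_NORMAL_LABEL, RRSeries

LF_FREQ_HZ = 0.10
HF_FREQ_HZ = 0.25


@dataclass(frozen=True)
class ConditionParams:
    """Tachogram parameters for one condition (all in ms)."""

    mean_rr: float
    a_lf: float  # LF oscillation amplitude
    a_hf: float  # HF (respiratory) oscillation amplitude
    noise_sd: float

    def validate(self):
        if not (400.0 <= self.mean_rr <= 1500.0):
            raise ValueError(f"mean RR {self.mean_rr} outside 400-1500 ms")
        if min(self.a_lf, self.a_hf, self.noise_sd) < 0:
            raise ValueError("amplitudes and noise SD must be >= 0")
        if self.a_lf + self.a_hf + 5 * self.noise_sd >= self.mean_rr:
            raise ValueError("parameters can produce non-positive RR intervals")


@dataclass(frozen=True)
class SubjectSpread:
    """Between-subject standard deviations of the tachogram parameters (ms)."""

    mean_rr: float = 60.0
    a_lf: float = 6.0
    a_hf: float = 10.0
    noise_sd: float = 5.0


@dataclass(frozen=True)
class CohortConfig:
    """Study-level generator settings.

    Defaults give a cohort of 42 subjects whose rest/stress contrast mirrors
    the expected stress physiology: MeanNN 850 -> 700 ms, HF-band amplitude
    40 -> 18 ms (HF power 800 -> ~160 ms^2), reduced LF amplitude and noise.
    Between-subject spreads are drawn once per subject around these means.
    """

    n_subjects: int = 42
    seed: int = 0
    rest: ConditionParams = ConditionParams(
        mean_rr=850.0, a_lf=30.0, a_hf=40.0, noise_sd=25.0
    )
    stress: ConditionParams = ConditionParams(
        mean_rr=700.0, a_lf=22.0, a_hf=18.0, noise_sd=24.0
    )
    between_subject_sd: SubjectSpread = SubjectSpread()
    artifact_rate: float = 0.0
    duration_s: float = 330.0  # a full 300-s excerpt survives edge trimming

    def validate(self):
        self.rest.validate()
        self.stress.validate()
        if not (0.0 <= self.artifact_rate <= 0.5):
            raise ValueError("artifact rate must lie in [0, 0.5]")


def generate_rr_series(
    params: ConditionParams,
    condition: Condition | str,
    duration_s: float = 330.0,
    seed: int | np.random.Generator = 0,
    subject_id: str = "S000",
    phases: tuple[float, float] | None = None,
) -> RRSeries:
    """One RR series: RR_i = mu + A_LF sin(2 pi 0.10 t + phi_LF)
    + A_HF sin(2 pi 0.25 t + phi_HF) + eps, t the cumulative beat time.

    Oscillation phases are drawn from the generator unless given. All beats
    are labelled normal; use inject_non_nn_beats to add artifacts.
    """
    params.validate()
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if phases is None:
        phases = tuple(rng.uniform(0, 2 * np.pi, size=2))
    phi_lf, phi_hf = phases
    times, rrs = [], []
    t = 0.0  # seconds
    while t < duration_s:
        rr = (
            params.mean_rr
            + params.a_lf * np.sin(2 * np.pi * LF_FREQ_HZ * t + phi_lf)
            + params.a_hf * np.sin(2 * np.pi * HF_FREQ_HZ * t + phi_hf)
            + params.noise_sd * rng.standard_normal()
        )
        if rr <= 0:
            raise ValueError("generated a non-positive RR interval")
        t += rr / 1000.0
        times.append(t * 1000.0)
        rrs.append(rr)
    n = len(rrs)
    return RRSeries(
        subject_id=subject_id,
        condition=Condition(condition),
        beat_times=np.array(times),
        rr_intervals=np.array(rrs),
        labels=np.array([NORMAL_LABEL] * n, dtype=object),
    )


def generate_cohort(config: CohortConfig = CohortConfig()) -> list[RRSeries]:
    """Paired rest/stress series for every subject, deterministic under seed.

    Subject-level parameters are drawn around the condition means with the
    configured between-subject spreads; the per-subject stress parameters are
    tied to the rest draw (the same subject offset applied to both), so the
    paired contrast is consistent within subjects.
    """
    config.validate()
    if config.n_subjects < 10:
        raise ValueError("need at least 10 subjects for downstream splitting")
    rng = np.random.default_rng(config.seed)
    out: list[RRSeries] = []
    for i in range(config.n_subjects):
        sid = f"S{i:03d}"
        # one standard-normal offset vector per subject, shared across
        # conditions so stress-minus-rest is the programmed contrast
        z = rng.standard_normal(4)
        sub_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        for cond, base in (("rest", config.rest), ("stress", config.stress)):
            p = ConditionParams(
                mean_rr=float(np.clip(
                    base.mean_rr + config.between_subject_sd.mean_rr * z[0],
                    450.0, 1450.0,
                )),
                a_lf=max(base.a_lf + config.between_subject_sd.a_lf * z[1], 0.0),
                a_hf=max(base.a_hf + config.between_subject_sd.a_hf * z[2], 1.0),
                noise_sd=max(
                    base.noise_sd + config.between_subject_sd.noise_sd * z[3], 1.0
                ),
            )
            series = generate_rr_series(
                p, cond, config.duration_s, sub_rng, subject_id=sid
            )
            if config.artifact_rate > 0:
                series = inject_non_nn_beats(
                    series, config.artifact_rate, sub_rng
                )
            out.append(series)
    return out


def inject_non_nn_beats(
    series: RRSeries, rate: float, seed: int | np.random.Generator = 0
) -> RRSeries:
    """Relabel a random fraction of beats as non-normal ectopics.

    Each selected beat is shifted earlier by 40% of its preceding interval (a
    premature beat), shortening the interval that ends on it and lengthening
    the next one by the same amount — a short-long couplet that keeps
    cumulative time consistent. Rate 0 returns the series unchanged.
    """
    if not (0.0 <= rate <= 0.5):
        raise ValueError("rate must lie in [0, 0.5]")
    if rate == 0.0 or len(series) < 3:
        return series
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = len(series)
    # interior beats only, so the couplet stays inside the record
    k = int(round(rate * n))
    if k == 0:
        return series
    idx = rng.choice(np.arange(1, n - 1), size=min(k, n - 2), replace=False)
    times = series.beat_times.copy()
    labels = series.labels.copy()
    for i in np.sort(idx):
        shift = 0.4 * (times[i] - times[i - 1])
        if times[i] - shift <= times[i - 1] or times[i] - shift >= times[i + 1]:
            continue
        times[i] -= shift
        labels[i] = NON_NORMAL_LABEL
    rrs = np.empty(n)
    rrs[0] = series.rr_intervals[0]
    rrs[1:] = np.diff(times)
    return RRSeries(
        subject_id=series.subject_id,
        condition=series.condition,
        beat_times=times,
        rr_intervals=rrs,
        labels=labels,
    )


def zero_contrast(config: CohortConfig = CohortConfig()) -> CohortConfig:
    """A null cohort: stress parameters identical to rest (no true effect)."""
    return replace(config, stress=config.rest)
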