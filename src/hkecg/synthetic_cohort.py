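"""Seeded synthetic single-lead ECG cohorts with potassium-dependent morphology.

Each heartbeat is modelled as the sum of five Gaussian bumps (P, Q, R, S, T),
a deliberately simple morphology model whose effect sizes are analytically
checkable.  Rising serum potassium is mapped to a severity score in [0, 1]
which drives the classic hyperkalemic ECG changes: T-wave peaking and
narrowing, QRS widening, P-wave flattening and PR lengthening.  Subjects
carry multiplicative log-normal random effects on wave amplitudes and widths
(and small additive shifts on wave centers), which produces the strong
intersubject morphology heterogeneity a generic beat classifier struggles
with and a personalized one is meant to overcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError

WAVE_NAMES = ("p", "q", "r", "s", "t")

#: potassium (mEq/L) below which morphology is unaffected / fully affected
SEVERITY_ONSET = 5.0
SEVERITY_SATURATION = 7.0

#: class bands used when truncating per-record potassium draws
NORMO_BAND = (3.5, 5.0)
HYPER_BAND = (5.5, 8.0)  # upper cap keeps the severity map meaningful


@dataclass(frozen=True)
class Wave:
    """One Gaussian bump: amplitude (mV), center (fraction of RR), width (s)."""

    amplitude: float
    center: float
    width: float


@dataclass(frozen=True)
class BeatTemplate:
    """Per-wave parameters for P, Q, R, S, T plus the RR-interval model."""

    p: Wave
    q: Wave
    r: Wave
    s: Wave
    t: Wave
    rr_mean: float = 0.8  # seconds
    rr_cv: float = 0.03  # dimensionless

    def __post_init__(self) -> None:
        centers = [getattr(self, n).center for n in WAVE_NAMES]
        if any(getattr(self, n).width <= 0 for n in WAVE_NAMES):
            raise InvalidArgumentError("wave widths must be positive")
        if not all(a < b for a, b in zip(centers, centers[1:])):
            raise InvalidArgumentError(
                "wave centers must be strictly ordered P < Q < R < S < T"
            )
        if not 0.4 <= self.rr_mean <= 2.0:
            raise InvalidArgumentError("RR mean must lie in [0.4, 2.0] s")
        if self.rr_cv < 0:
            raise InvalidArgumentError("RR coefficient of variation must be >= 0")

    @property
    def waves(self) -> dict[str, Wave]:
        return {n: getattr(self, n) for n in WAVE_NAMES}


#: a lead-II-like resting template (R-dominant, upright T)
DEFAULT_TEMPLATE = BeatTemplate(
    p=Wave(0.12, 0.22, 0.040),
    q=Wave(-0.10, 0.37, 0.012),
    r=Wave(1.00, 0.40, 0.014),
    s=Wave(-0.20, 0.43, 0.014),
    t=Wave(0.30, 0.56, 0.070),
    rr_mean=0.8,
    rr_cv=0.03,
)


@dataclass(frozen=True)
class SeverityResponse:
    """Dimensionless severity-response coefficients (all >= 0).

    At severity ``s`` the rendered beat applies:
    T amplitude x (1 + t_gain*s), T width x (1 - t_width_shrink*s),
    QRS widths x (1 + qrs_widen*s), P amplitude x (1 - p_loss*s),
    P-to-R spacing x (1 + pr_stretch*s).
    """

    t_gain: float = 0.8
    t_width_shrink: float = 0.3
    qrs_widen: float = 0.4
    p_loss: float = 0.6
    pr_stretch: float = 0.25

    def __post_init__(self) -> None:
        for name in ("t_gain", "t_width_shrink", "qrs_widen", "p_loss", "pr_stretch"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"severity coefficient {name} must be >= 0")


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    template: BeatTemplate
    response: SeverityResponse = field(default_factory=SeverityResponse)
    noise_sd: float = 0.03  # mV, additive white noise
    wander_amplitude: float = 0.10  # mV
    wander_frequency: float = 0.30  # Hz (respiration-like baseline drift)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise sd must be >= 0")
        if self.wander_amplitude < 0 or self.wander_frequency < 0:
            raise InvalidArgumentError("baseline wander parameters must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 16
    records_per_class: int = 8
    duration_s: float = 600.0
    fs: float = 125.0
    subject_spread: float = 0.3  # sd of log-normal subject random effects
    normo_mean: float = 4.3  # Table-style class means (mEq/L)
    normo_sd: float = 0.40
    hyper_mean: float = 6.3
    hyper_sd: float = 0.64
    noise_sd: float = 0.03
    wander_amplitude: float = 0.10
    wander_frequency: float = 0.30
    rr_cv: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.records_per_class < 1:
            raise InvalidArgumentError("cohort must have >= 1 subject and record")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise InvalidArgumentError("duration x frequency must be an integer")
        if not NORMO_BAND[0] <= self.normo_mean <= NORMO_BAND[1]:
            raise InvalidArgumentError("normokalemic mean outside [3.5, 5.0]")
        if not HYPER_BAND[0] < self.hyper_mean <= HYPER_BAND[1]:
            raise InvalidArgumentError("hyperkalemic mean outside (5.5, 8.0]")
        if self.subject_spread < 0 or self.noise_sd < 0:
            raise InvalidArgumentError("spread and noise sd must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass
class EcgRecord:
    """One subject's single-lead waveform paired with one lab draw."""

    record_id: str
    subject_id: str
    signal: np.ndarray  # mV
    fs: float
    potassium: float  # mEq/L
    timestamp: datetime
    r_peaks: np.ndarray | None = None  # generator ground truth (sample indices)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise InvalidArgumentError("sampling frequency must be positive")
        self.signal = np.asarray(self.signal, dtype=float)


def severity(potassium: float) -> float:
    """Map serum potassium to a morphology severity score in [0, 1].

    Piecewise linear: 0 at or below 5.0 mEq/L, 1 at or above 7.0 mEq/L.
    """
    if potassium <= 0:
        raise InvalidArgumentError("potassium must be positive")
    x = (potassium - SEVERITY_ONSET) / (SEVERITY_SATURATION - SEVERITY_ONSET)
    return float(min(1.0, max(0.0, x)))


def _severity_adjusted(template: BeatTemplate, s: float, response: SeverityResponse
                       ) -> BeatTemplate:
    if not 0.0 <= s <= 1.0:
        raise InvalidArgumentError("severity must lie in [0, 1]")
    if s == 0.0:
        return template
    w = template.waves
    pr = w["r"].center - w["p"].center
    new_p_center = w["r"].center - pr * (1.0 + response.pr_stretch * s)
    return replace(
        template,
        p=replace(w["p"], amplitude=w["p"].amplitude * (1.0 - response.p_loss * s),
                  center=new_p_center),
        q=replace(w["q"], width=w["q"].width * (1.0 + response.qrs_widen * s)),
        r=replace(w["r"], width=w["r"].width * (1.0 + response.qrs_widen * s)),
        s=replace(w["s"], width=w["s"].width * (1.0 + response.qrs_widen * s)),
        t=replace(w["t"], amplitude=w["t"].amplitude * (1.0 + response.t_gain * s),
                  width=w["t"].width * (1.0 - response.t_width_shrink * s)),
    )


def render_beat(template: BeatTemplate, severity_score: float, rr: float, fs: float,
                response: SeverityResponse | None = None) -> np.ndarray:
    """Render one beat: five Gaussian bumps on an fs-spaced grid of length
    round(rr * fs).  ``severity_score`` 0 reproduces the template unchanged."""
    n = int(round(rr * fs))
    if n < 20:
        raise InvalidArgumentError("rr x fs must be at least 20 samples")
    tpl = _severity_adjusted(template, severity_score, response or SeverityResponse())
    t = np.arange(n) / fs
    out = np.zeros(n)
    for wave in tpl.waves.values():
        out += wave.amplitude * np.exp(-0.5 * ((t - wave.center * rr) / wave.width) ** 2)
    return out


def r_sample_offset(template: BeatTemplate, rr: float, fs: float) -> int:
    """Sample index of the R-wave center inside one rendered beat."""
    return int(round(template.r.center * rr * fs))


def subject_rng(master_seed: int, subject_index: int) -> np.random.Generator:
    """Per-subject generator: master seed + subject index via SeedSequence
    spawn keys, so adding subjects never perturbs earlier ones."""
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(subject_index,))
    )


def _lognormal(rng: np.random.Generator, spread: float) -> float:
    return float(np.exp(rng.normal(0.0, spread))) if spread > 0 else 1.0


def sample_profile(rng: np.random.Generator, config: CohortConfig,
                   subject_id: str) -> SubjectProfile:
    """Draw one subject's random effects around the default template."""
    spread = config.subject_spread
    base = DEFAULT_TEMPLATE
    waves = {}
    center_jitter_sd = 0.015 * spread
    prev_center = 0.0
    for name in WAVE_NAMES:
        w = base.waves[name]
        amp = w.amplitude * _lognormal(rng, spread)
        width = w.width * _lognormal(rng, spread)
        center = w.center + rng.normal(0.0, center_jitter_sd)
        # keep the strict P < Q < R < S < T ordering invariant
        center = max(center, prev_center + 0.005)
        waves[name] = Wave(amp, center, width)
        prev_center = center
    rr_mean = float(np.clip(base.rr_mean * _lognormal(rng, 0.5 * spread), 0.45, 1.8))
    template = BeatTemplate(rr_mean=rr_mean, rr_cv=config.rr_cv, **waves)
    resp = SeverityResponse()
    resp = SeverityResponse(
        t_gain=resp.t_gain * _lognormal(rng, 0.5 * spread),
        t_width_shrink=min(0.6, resp.t_width_shrink * _lognormal(rng, 0.5 * spread)),
        qrs_widen=resp.qrs_widen * _lognormal(rng, 0.5 * spread),
        p_loss=min(1.0, resp.p_loss * _lognormal(rng, 0.5 * spread)),
        pr_stretch=resp.pr_stretch * _lognormal(rng, 0.5 * spread),
    )
    return SubjectProfile(
        subject_id=subject_id,
        template=template,
        response=resp,
        noise_sd=config.noise_sd * _lognormal(rng, spread),
        wander_amplitude=config.wander_amplitude * _lognormal(rng, spread),
        wander_frequency=config.wander_frequency * _lognormal(rng, 0.5 * spread),
    )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float, low_open: bool = False) -> float:
    for _ in range(10_000):
        x = float(rng.normal(mean, sd)) if sd > 0 else mean
        if (low < x if low_open else low <= x) and x <= high:
            return x
    raise InvalidArgumentError(
        f"potassium distribution N({mean}, {sd}) incompatible with band "
        f"[{low}, {high}]"
    )


def generate_record(profile: SubjectProfile, potassium: float, config: CohortConfig,
                    rng: np.random.Generator, record_id: str,
                    timestamp: datetime) -> EcgRecord:
    """Concatenate severity-adjusted beats with RR jitter, then add baseline
    wander and white noise.  Ground-truth R-peak sample indices are kept."""
    n_total = config.n_samples
    fs = config.fs
    sev = severity(potassium)
    tpl = profile.template
    chunks: list[np.ndarray] = []
    r_locs: list[int] = []
    offset = 0
    while offset < n_total:
        rr = tpl.rr_mean * (1.0 + tpl.rr_cv * float(rng.standard_normal()))
        rr = max(rr, 0.3)
        beat = render_beat(tpl, sev, rr, fs, profile.response)
        r_locs.append(offset + r_sample_offset(tpl, rr, fs))
        chunks.append(beat)
        offset += beat.size
    signal = np.concatenate(chunks)[:n_total]
    t = np.arange(n_total) / fs
    if profile.wander_amplitude > 0:
        phase = rng.uniform(0.0, 2.0 * math.pi)
        signal = signal + profile.wander_amplitude * np.sin(
            2.0 * math.pi * profile.wander_frequency * t + phase
        )
    if profile.noise_sd > 0:
        signal = signal + rng.normal(0.0, profile.noise_sd, size=n_total)
    r_peaks = np.array([r for r in r_locs if r < n_total], dtype=int)
    return EcgRecord(record_id=record_id, subject_id=profile.subject_id,
                     signal=signal, fs=fs, potassium=potassium,
                     timestamp=timestamp, r_peaks=r_peaks)


def generate_cohort(config: CohortConfig
                    ) -> list[tuple[SubjectProfile, list[EcgRecord]]]:
    """Generate the full cohort, deterministic in ``config.seed``.

    Every subject contributes ``records_per_class`` normokalemic and
    ``records_per_class`` hyperkalemic records; per-record potassium is drawn
    from the class distribution truncated to the class band (normo [3.5, 5.0],
    hyper (5.5, 8.0]).
    """
    cohort = []
    t0 = datetime(2020, 1, 1, 8, 0, 0)
    for i in range(config.n_subjects):
        rng = subject_rng(config.seed, i)
        subject_id = f"S{i:03d}"
        profile = sample_profile(rng, config, subject_id)
        records = []
        k = 0
        for class_name, (mean, sd, band, low_open) in {
            "normo": (config.normo_mean, config.normo_sd, NORMO_BAND, False),
            "hyper": (config.hyper_mean, config.hyper_sd, HYPER_BAND, True),
        }.items():
            for j in range(config.records_per_class):
                potassium = _truncated_normal(rng, mean, sd, band[0], band[1],
                                              low_open=low_open)
                rec = generate_record(
                    profile, potassium, config, rng,
                    record_id=f"{subject_id}_{class_name}{j:02d}",
                    timestamp=t0 + timedelta(days=i, hours=6 * k),
                )
                records.append(rec)
                k += 1
        cohort.append((profile, records))
    return cohort


def separable_config(**overrides) -> CohortConfig:
    """Noise-free, homogeneous cohort: classes separable from T morphology."""
    base = dict(n_subjects=12, records_per_class=2, duration_s=20.0, fs=125.0,
                subject_spread=0.0, noise_sd=0.0, wander_amplitude=0.0, seed=0)
    base.update(overrides)
    return CohortConfig(**base)


def heterogeneous_config(**overrides) -> CohortConfig:
    """Strong intersubject heterogeneity: the regime personalized transfer
    learning exists for (between-subject morphology variance dominates
    within-subject variance)."""
    base = dict(n_subjects=8, records_per_class=8, duration_s=30.0, fs=125.0,
                subject_spread=0.5, noise_sd=0.02, wander_amplitude=0.05, seed=0)
    base.update(overrides)
    return CohortConfig(**base)
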