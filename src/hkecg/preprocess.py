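"""Raw-ECG preprocessing: band-limiting, quality control, R-peak detection,
beat segmentation and potassium labelling.

The beat geometry is fixed by the study design: each beat is 120 samples with
the R peak at the 41st sample (1-based), i.e. 40 samples before and 80 after
the fiducial point.  Records are labelled from the paired serum potassium:
hyperkalemia above 5.5 mEq/L, normokalemia within [3.5, 5.0] mEq/L, and the
ambiguous band (5.0, 5.5] (plus hypokalemia below 3.5) excluded so no beat
can be counted as both classes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
from scipy import signal as sps

from .errors import InvalidArgumentError, MissingDataError
from .synthetic_cohort import EcgRecord

BEAT_LENGTH = 120
PRE_SAMPLES = 40  # samples before the R peak
POST_SAMPLES = 80  # samples from the R peak onward
FIDUCIAL_POSITION = 41  # 1-based position of the R peak within a beat
EXCERPT_SECONDS = 600.0  # the 10 minutes preceding a lab draw


class Label(str, enum.Enum):
    HYPER = "hyper"
    NORMO = "normo"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase FIR band-pass specification."""

    low_hz: float = 0.5
    high_hz: float = 40.0
    taps: int = 255
    window: str = "hamming"

    def validate(self, fs: float) -> None:
        if not 0 < self.low_hz < self.high_hz < fs / 2:
            raise InvalidArgumentError(
                f"passband ({self.low_hz}, {self.high_hz}) Hz invalid for fs={fs}"
            )
        if self.taps % 2 == 0:
            raise InvalidArgumentError("tap count must be odd")


@dataclass(frozen=True)
class QCConfig:
    """Automated surrogate for manual noise inspection."""

    max_flat_fraction: float = 0.1
    max_oob_power_ratio: float = 0.5  # out-of-band / in-band power
    max_rr_cv: float = 0.25  # rhythm-regularity surrogate
    band: tuple[float, float] = (0.5, 40.0)


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reason: str | None = None
    details: dict = field(default_factory=dict)


@dataclass
class Beat:
    """A 120-sample segmented heartbeat; fiducial R at 1-based index 41."""

    record_id: str
    samples: np.ndarray
    label: Label | None = None
    r_position: int = FIDUCIAL_POSITION

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (BEAT_LENGTH,):
            raise InvalidArgumentError("a beat must contain exactly 120 samples")


@dataclass
class LabeledRecord:
    record_id: str
    subject_id: str
    potassium: float
    label: Label
    signal: np.ndarray
    fs: float
    short_window: bool = False

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.size > int(round(EXCERPT_SECONDS * self.fs)):
            raise InvalidArgumentError("excerpt exceeds the 600 s window")


def design_fir(spec: FilterSpec, fs: float) -> np.ndarray:
    spec.validate(fs)
    return sps.firwin(spec.taps, [spec.low_hz, spec.high_hz],
                      window=spec.window, pass_zero=False, fs=fs)


def fir_filter(x: np.ndarray, fs: float, spec: FilterSpec | None = None
               ) -> np.ndarray:
    """Zero-phase FIR band-pass (forward-backward); output length = input."""
    spec = spec or FilterSpec()
    x = np.asarray(x, dtype=float)
    if x.size <= spec.taps:
        raise InvalidArgumentError("signal must be longer than the filter")
    taps = design_fir(spec, fs)
    padlen = min(3 * spec.taps, x.size - 1)
    return sps.filtfilt(taps, [1.0], x, padlen=padlen)


def _band_power_split(x: np.ndarray, fs: float, band: tuple[float, float]
                      ) -> tuple[float, float]:
    """(in-band, out-of-band) power via the periodogram (Parseval-exact)."""
    freqs, psd = sps.periodogram(x, fs=fs, window="boxcar", detrend=False)
    inband = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.sum(psd[inband])), float(np.sum(psd[~inband]))


def quality_check(x: np.ndarray, fs: float, config: QCConfig | None = None
                  ) -> QCResult:
    """Automated record QC on the raw excerpt, before band-pass filtering.

    Fails when (a) too many samples are flat/clipped, (b) the ratio of power
    outside the monitoring band to power inside it is too high (broadband
    noise), or (c) the detected RR series is too irregular to define a beat
    cycle (rhythms such as atrial fibrillation are rejected here rather than
    by diagnosis codes).
    """
    config = config or QCConfig()
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return QCResult(False, "too_short")
    flat_fraction = float(np.mean(np.abs(np.diff(x)) < 1e-9))
    if flat_fraction > config.max_flat_fraction:
        return QCResult(False, "flat", {"flat_fraction": flat_fraction})
    p_in, p_out = _band_power_split(x, fs, config.band)
    oob_ratio = p_out / p_in if p_in > 0 else np.inf
    if oob_ratio > config.max_oob_power_ratio:
        return QCResult(False, "out_of_band_noise", {"oob_power_ratio": oob_ratio})
    try:
        peaks = detect_rpeaks(fir_filter(x, fs), fs)
    except InvalidArgumentError:
        peaks = np.array([], dtype=int)
    if peaks.size >= 3:
        rr = np.diff(peaks) / fs
        rr_cv = float(np.std(rr) / np.mean(rr))
        if rr_cv > config.max_rr_cv:
            return QCResult(False, "irregular_rhythm", {"rr_cv": rr_cv})
    else:
        return QCResult(False, "no_beats", {"n_peaks": int(peaks.size)})
    return QCResult(True, None, {"flat_fraction": flat_fraction,
                                 "oob_power_ratio": oob_ratio})


def detect_rpeaks(x: np.ndarray, fs: float) -> np.ndarray:
    """Pan-Tompkins-style R-peak detector.

    Stages: 5-15 Hz band-pass, five-point derivative, squaring, 150 ms
    moving-window integration, adaptive signal/noise thresholding with a
    200 ms refractory period, then fiducial refinement to the local maximum
    of the input signal.  Returns strictly increasing sample indices.
    """
    x = np.asarray(x, dtype=float)
    if x.size < int(fs):
        raise InvalidArgumentError("signal shorter than one second")
    if np.ptp(x) == 0:
        return np.array([], dtype=int)

    # band-pass emphasising the QRS complex
    ntaps = int(2 * round(0.2 * fs) + 1)
    bp = sps.firwin(ntaps, [5.0, 15.0], pass_zero=False, fs=fs)
    filtered = sps.filtfilt(bp, [1.0], x, padlen=min(3 * ntaps, x.size - 1))
    # derivative (five-point), squaring, moving-window integration
    deriv = np.convolve(filtered, np.array([1, 2, 0, -2, -1]) * fs / 8.0, "same")
    squared = deriv**2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, "same")

    refractory = int(round(0.200 * fs))
    candidates, _ = sps.find_peaks(mwi, distance=refractory)
    if candidates.size == 0:
        return np.array([], dtype=int)

    head = mwi[: int(2 * fs)] if mwi.size >= int(2 * fs) else mwi
    spki = float(np.max(head)) * 0.5
    npki = float(np.mean(head)) * 0.5
    accepted = []
    for c in candidates:
        threshold = npki + 0.25 * (spki - npki)
        if mwi[c] > threshold:
            accepted.append(c)
            spki = 0.125 * mwi[c] + 0.875 * spki
        else:
            npki = 0.125 * mwi[c] + 0.875 * npki

    # refine each detection to the true R location on the input signal
    half = int(round(0.10 * fs))
    refined = []
    for c in accepted:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(np.asarray(refined, dtype=int))
    if refined.size > 1:  # enforce the refractory period after refinement
        keep = [int(refined[0])]
        for r in refined[1:]:
            if r - keep[-1] >= refractory:
                keep.append(int(r))
            elif x[r] > x[keep[-1]]:
                keep[-1] = int(r)
        refined = np.asarray(keep, dtype=int)
    return refined


def segment_beats(x: np.ndarray, rpeaks: np.ndarray, record_id: str = "",
                  label: Label | None = None) -> list[Beat]:
    """Cut [r-40, r+80) windows; drop R peaks too close to either edge."""
    x = np.asarray(x, dtype=float)
    rpeaks = np.asarray(rpeaks, dtype=int)
    if rpeaks.size and np.any(np.diff(rpeaks) <= 0):
        raise InvalidArgumentError("R-peak indices must be strictly increasing")
    beats = []
    for r in rpeaks:
        if r - PRE_SAMPLES < 0 or r + POST_SAMPLES > x.size:
            continue
        beats.append(Beat(record_id=record_id,
                          samples=x[r - PRE_SAMPLES: r + POST_SAMPLES],
                          label=label))
    return beats


def label_potassium(potassium: float) -> Label:
    """Deterministic class label from serum potassium (mEq/L)."""
    if potassium <= 0:
        raise InvalidArgumentError("potassium must be positive")
    if potassium > 5.5:
        return Label.HYPER
    if 3.5 <= potassium <= 5.0:
        return Label.NORMO
    return Label.EXCLUDED


def extract_excerpt(signal: np.ndarray, fs: float, record_start: datetime,
                    draw_time: datetime) -> tuple[np.ndarray, bool]:
    """The (up to) 600 s of waveform ending at the lab-draw time.

    Returns (excerpt, short_window); ``short_window`` is True when less than
    the full 10 minutes was available before the draw.
    """
    signal = np.asarray(signal, dtype=float)
    record_end = record_start + timedelta(seconds=signal.size / fs)
    if draw_time <= record_start:
        raise MissingDataError("lab draw precedes the start of the recording")
    if draw_time > record_end + timedelta(seconds=1.0 / fs):
        raise MissingDataError("recording ends before the lab draw")
    end = int(round((draw_time - record_start).total_seconds() * fs))
    end = min(end, signal.size)
    start = max(0, end - int(round(EXCERPT_SECONDS * fs)))
    return signal[start:end], (end - start) < int(round(EXCERPT_SECONDS * fs))


def preprocess_record(record: EcgRecord, filter_spec: FilterSpec | None = None,
                      qc: QCConfig | None = None, run_qc: bool = True
                      ) -> tuple[LabeledRecord, list[Beat], QCResult | None]:
    """Full per-record pipeline: QC (raw), zero-phase filter, R detection,
    segmentation, potassium labelling.  QC failures return an empty beat
    list; excluded-band records keep their beats but carry Label.EXCLUDED."""
    label = label_potassium(record.potassium)
    qc_result = quality_check(record.signal, record.fs, qc) if run_qc else None
    filtered = fir_filter(record.signal, record.fs, filter_spec)
    labeled = LabeledRecord(record_id=record.record_id,
                            subject_id=record.subject_id,
                            potassium=record.potassium, label=label,
                            signal=filtered, fs=record.fs)
    if qc_result is not None and not qc_result.passed:
        return labeled, [], qc_result
    rpeaks = detect_rpeaks(filtered, record.fs)
    beats = segment_beats(filtered, rpeaks, record.record_id, label)
    return labeled, beats, qc_result
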