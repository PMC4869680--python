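"""Heartbeat identification from raw cardiac waveforms.

Two detectors are provided:

* :func:`detect_qrs` — an offline Pan–Tompkins QRS detector for
  single-channel ECG: zero-phase band-pass (5–15 Hz), differentiation,
  squaring, 150 ms moving-window integration, adaptive dual thresholds
  with search-back, a 200 ms refractory period, and a final R-peak
  refinement pass on the raw signal.
* :func:`detect_pulse_peaks` — a template-matching detector for
  peripheral-pulse (pulse-oximetry) waveforms: a template is averaged
  from peaks with prominence above one third of the signal amplitude
  and at least 0.3 s away from neighbouring peaks, then beats are
  placed at local maxima of the normalized cross-correlation between
  template and signal.

Downstream analysis only consumes beat *times*; a constant
pulse-transit lag between ECG and peripheral pulse cancels in interbeat
intervals and is therefore irrelevant.

Interbeat intervals (IBIs) deviating by more than a configurable number
of standard deviations from the subject mean can be flagged
(:func:`flag_ibis`) and automatically repaired (:func:`correct_ibis`)
with an auditable correction log.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .exceptions import (
    NoBeatsError,
    QualityError,
    TemplateFailureError,
    UnsupportedRateError,
    ValidationError,
)

__all__ = [
    "Waveform",
    "BeatTimes",
    "detect_qrs",
    "detect_pulse_peaks",
    "flag_ibis",
    "correct_ibis",
]

#: flag values carried per beat
CLEAN, FLAGGED, CORRECTED = "clean", "flagged", "corrected"

#: physiological refractory period between beats (s)
REFRACTORY_S = 0.2

#: minimum pulse-peak spacing for template eligibility and beat placement (s)
MIN_PULSE_SPACING_S = 0.3


@dataclass(frozen=True)
class Waveform:
    """Single-channel cardiac waveform on the session clock.

    Parameters
    ----------
    samples:
        Amplitude values, arbitrary units.
    fs:
        Sampling rate in Hz.
    modality:
        ``"ecg"`` or ``"pps"`` (peripheral pulse sensor).
    t0:
        Time of the first sample on the session clock (s).
    """

    samples: np.ndarray
    fs: float
    modality: str
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if samples.size == 0:
            raise ValidationError("waveform has no samples")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("waveform contains non-finite samples")
        if self.modality not in ("ecg", "pps"):
            raise ValidationError(f"unknown modality {self.modality!r}")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class BeatTimes:
    """Ordered heartbeat timestamps with per-beat artifact flags."""

    times: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    source: str = "file"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if self.flags is None:
            object.__setattr__(self, "flags", np.full(times.size, CLEAN, dtype=object))
        else:
            flags = np.asarray(self.flags, dtype=object)
            if flags.size != times.size:
                raise ValidationError("flags and times length mismatch")
            object.__setattr__(self, "flags", flags)
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ValidationError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def ibis(self) -> np.ndarray:
        """Interbeat intervals (s); IBI i belongs to beat i+1 (its *following* beat)."""
        return np.diff(self.times)


# ---------------------------------------------------------------------------
# Pan–Tompkins QRS detection (offline variant)
# ---------------------------------------------------------------------------


def _moving_window_integral(x: np.ndarray, fs: float, width_s: float = 0.150) -> np.ndarray:
    w = max(int(round(width_s * fs)), 1)
    kernel = np.ones(w) / w
    # centred window: keeps the energy peak aligned with the R wave
    return np.convolve(x, kernel, mode="same")


def detect_qrs(wave: Waveform) -> BeatTimes:
    """Detect QRS complexes in a single-channel ECG.

    Offline Pan–Tompkins: because the data are analysed after the
    recording, both the band-pass stage and the moving-window
    integration are zero-phase/centred, and detected events are refined
    to the R peak on the raw signal in a second pass.

    Returns one timestamp per QRS complex at the R-peak sample. No two
    beats are closer than the 0.2 s refractory period.

    Raises
    ------
    UnsupportedRateError
        If ``wave.fs`` < 100 Hz.
    NoBeatsError
        If the signal is flat or no QRS-like events are found.
    """
    if wave.modality != "ecg":
        raise ValidationError(f"detect_qrs expects an ECG waveform, got {wave.modality!r}")
    if wave.fs < 100:
        raise UnsupportedRateError(f"sampling rate {wave.fs} Hz too low for QRS detection (need >= 100 Hz)")

    x = wave.samples
    fs = wave.fs
    if np.ptp(x) == 0:
        raise NoBeatsError("flat signal: no QRS complexes found")

    # 1) band-pass 5-15 Hz, zero phase
    sos = sps.butter(2, [5.0, 15.0], btype="band", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    # 2-4) derivative, squaring, moving-window integration
    deriv = np.gradient(bp) * fs
    mwi = _moving_window_integral(deriv**2, fs)

    refractory = int(round(REFRACTORY_S * fs))
    peaks, _ = sps.find_peaks(mwi, distance=refractory)
    if peaks.size == 0:
        raise NoBeatsError("no candidate peaks in integrated signal")

    # adaptive dual thresholds with search-back
    init = mwi[: min(int(2 * fs), mwi.size)]
    spki = 0.5 * float(np.max(init))
    npki = 0.5 * float(np.mean(init))
    qrs: list[int] = []
    noise_peaks: list[int] = []
    rr_history: list[float] = []

    for p in peaks:
        threshold = npki + 0.25 * (spki - npki)
        if mwi[p] > threshold:
            qrs.append(p)
            spki = 0.125 * mwi[p] + 0.875 * spki
            if len(qrs) >= 2:
                rr_history.append((qrs[-1] - qrs[-2]) / fs)
                rr_history = rr_history[-8:]
        else:
            noise_peaks.append(p)
            npki = 0.125 * mwi[p] + 0.875 * npki
            # search-back: if the expected beat is overdue, accept the
            # largest skipped peak above half threshold
            if rr_history and qrs:
                mean_rr = float(np.mean(rr_history))
                if (p - qrs[-1]) / fs > 1.66 * mean_rr:
                    cand = [q for q in noise_peaks if q > qrs[-1] and mwi[q] > 0.5 * threshold]
                    if cand:
                        best = max(cand, key=lambda q: mwi[q])
                        qrs.append(best)
                        qrs.sort()
                        spki = 0.25 * mwi[best] + 0.75 * spki

    if not qrs:
        raise NoBeatsError("no peaks exceeded the adaptive threshold")

    # refinement pass: locate the R peak on the raw signal near each event
    half = int(round(0.100 * fs))
    baseline = float(np.median(x))
    refined = []
    for p in qrs:
        lo, hi = max(p - half, 0), min(p + half + 1, x.size)
        refined.append(lo + int(np.argmax(np.abs(x[lo:hi] - baseline))))
    refined = np.unique(refined)

    # enforce refractory after refinement (keep the larger raw deflection)
    kept: list[int] = []
    for r in refined:
        if kept and (r - kept[-1]) / fs < REFRACTORY_S:
            if abs(x[r] - baseline) > abs(x[kept[-1]] - baseline):
                kept[-1] = r
        else:
            kept.append(r)

    times = wave.t0 + np.asarray(kept, dtype=float) / fs
    return BeatTimes(times=times, source="ecg")


# ---------------------------------------------------------------------------
# Peripheral pulse template matching
# ---------------------------------------------------------------------------


def _signal_amplitude(x: np.ndarray) -> float:
    """Robust peak-to-peak amplitude (1st-99th percentile span).

    Percentiles keep single large artifact spikes from inflating the
    prominence criterion for ordinary pulse peaks.
    """
    lo, hi = np.percentile(x, [1.0, 99.0])
    return float(hi - lo)


def _normalized_xcorr(x: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Sliding-window Pearson correlation of ``template`` against ``x``.

    Returns one value per valid offset (length ``len(x) - len(template) + 1``).
    """
    m = template.size
    t = template - template.mean()
    t_norm = float(np.sqrt(np.sum(t**2)))
    if t_norm == 0:
        raise TemplateFailureError("template has zero variance")
    ones = np.ones(m)
    s1 = np.convolve(x, ones, mode="valid")  # running sum
    s2 = np.convolve(x**2, ones, mode="valid")  # running sum of squares
    num = np.correlate(x, t, mode="valid")
    var = np.maximum(s2 - s1**2 / m, 0.0)
    denom = np.sqrt(var) * t_norm
    ncc = np.zeros_like(num)
    good = denom > 0
    ncc[good] = num[good] / denom[good]
    return ncc


def detect_pulse_peaks(wave: Waveform, ncc_threshold: float = 0.5) -> BeatTimes:
    """Detect heartbeats in a peripheral-pulse waveform by template matching.

    A pulse template is built as the average waveform (one mean-IBI
    window) around peaks satisfying both eligibility conditions: a
    prominence higher than one third of the signal amplitude, and a
    distance above 0.3 s from neighbouring candidate peaks. Beats are
    then placed at local maxima of the normalized cross-correlation
    between template and signal, with a minimum spacing of 0.3 s.

    The absolute beat times include the pulse-transit lag relative to
    the electrical heartbeat; this constant phase offset cancels in
    interbeat intervals and does not affect downstream modelling.

    Raises
    ------
    TemplateFailureError
        If fewer than 3 template-eligible peaks exist.
    """
    if wave.modality != "pps":
        raise ValidationError(f"detect_pulse_peaks expects a PPS waveform, got {wave.modality!r}")
    x = wave.samples
    fs = wave.fs
    amp = _signal_amplitude(x)
    if amp == 0:
        raise TemplateFailureError("flat signal: no pulse peaks")

    candidates, props = sps.find_peaks(x, prominence=amp / 3.0)
    if candidates.size < 3:
        raise TemplateFailureError(f"only {candidates.size} prominent peaks; need >= 3 for a template")

    # spacing eligibility: farther than 0.3 s from BOTH neighbouring candidates
    min_gap = MIN_PULSE_SPACING_S * fs
    gaps_prev = np.diff(candidates, prepend=candidates[0] - int(2 * min_gap))
    gaps_next = np.diff(candidates, append=candidates[-1] + int(2 * min_gap))
    eligible = candidates[(gaps_prev > min_gap) & (gaps_next > min_gap)]
    if eligible.size < 3:
        raise TemplateFailureError(
            f"only {eligible.size} peaks satisfy prominence and 0.3 s spacing; need >= 3"
        )

    # template: one mean-IBI window centred on each eligible peak
    mean_ibi = float(np.median(np.diff(eligible))) / fs
    half = max(int(round(mean_ibi * fs / 2)), int(round(0.1 * fs)))
    windows = [
        x[p - half : p + half + 1]
        for p in eligible
        if p - half >= 0 and p + half + 1 <= x.size
    ]
    if len(windows) < 3:
        raise TemplateFailureError("fewer than 3 full template windows inside the recording")
    template = np.mean(windows, axis=0)

    ncc = _normalized_xcorr(x, template)
    spacing = int(round(MIN_PULSE_SPACING_S * fs))
    ncc_peaks, _ = sps.find_peaks(ncc, height=ncc_threshold, distance=spacing)
    if ncc_peaks.size == 0:
        raise NoBeatsError("no correlation maxima above threshold")

    beat_idx = ncc_peaks + half  # window centre = pulse peak position
    times = wave.t0 + beat_idx.astype(float) / fs
    return BeatTimes(times=times, source="pps")


# ---------------------------------------------------------------------------
# IBI flagging and correction
# ---------------------------------------------------------------------------


def flag_ibis(beats: BeatTimes, sd_threshold: float = 2.0) -> BeatTimes:
    """Flag beats whose IBI deviates from the subject mean by > ``sd_threshold`` SD.

    The IBI is assigned to its following beat, so the flag lands on the
    later beat of each deviant pair. Values are untouched. With fewer
    than 3 beats (or zero IBI variance) everything stays clean.
    """
    if len(beats) < 3:
        return replace(beats, flags=np.full(len(beats), CLEAN, dtype=object))
    ibis = beats.ibis
    mean, sd = float(np.mean(ibis)), float(np.std(ibis))
    flags = np.full(len(beats), CLEAN, dtype=object)
    if sd > 0:
        deviant = np.abs(ibis - mean) > sd_threshold * sd
        flags[1:][deviant] = FLAGGED
    return replace(beats, flags=flags)


def correct_ibis(
    beats: BeatTimes,
    policy: str = "interpolate",
    max_flag_fraction: float = 0.5,
) -> tuple[BeatTimes, list[str]]:
    """Repair flagged interbeat intervals; returns (beats, correction log).

    Policies
    --------
    ``interpolate``
        Replace each flagged IBI by linear interpolation of the
        neighbouring clean IBIs (in IBI-index space) and re-derive beat
        times cumulatively from the first beat.
    ``merge_split``
        Anchor on the clean beats surrounding each flagged run and
        redistribute beats inside the gap: the number of sub-intervals
        is chosen so each is close to the local clean IBI, which
        inserts a midpoint beat for a doubled IBI (missed beat) and
        merges beats for halved IBIs (spurious detection). Clean beat
        times are preserved, so event alignment is unaffected.
    ``none``
        Leave values untouched (log only).

    Raises
    ------
    QualityError
        If more than ``max_flag_fraction`` of IBIs are flagged.
    """
    if policy not in ("interpolate", "merge_split", "none"):
        raise ValidationError(f"unknown correction policy {policy!r}")
    flags = np.asarray(beats.flags, dtype=object)
    flagged_beats = np.flatnonzero(flags == FLAGGED)
    if flagged_beats.size == 0:
        return replace(beats), ["no flagged IBIs; nothing to correct"]
    n_ibis = max(len(beats) - 1, 1)
    frac = flagged_beats.size / n_ibis
    if frac > max_flag_fraction:
        raise QualityError(
            f"{frac:.0%} of IBIs flagged exceeds the {max_flag_fraction:.0%} repair limit"
        )

    log = [f"policy={policy}: {flagged_beats.size}/{n_ibis} IBIs flagged ({frac:.1%})"]
    if policy == "none":
        return replace(beats), log

    ibis = beats.ibis.copy()
    flagged_ibi_idx = flagged_beats - 1  # IBI i belongs to beat i+1

    if policy == "interpolate":
        clean_idx = np.setdiff1d(np.arange(ibis.size), flagged_ibi_idx)
        if clean_idx.size == 0:
            raise QualityError("no clean IBIs left to interpolate from")
        new_vals = np.interp(flagged_ibi_idx, clean_idx, ibis[clean_idx])
        for i, v in zip(flagged_ibi_idx, new_vals):
            log.append(
                f"IBI {i} at t={beats.times[i + 1]:.3f}s: {ibis[i]:.3f}s -> {v:.3f}s (interpolated)"
            )
        ibis[flagged_ibi_idx] = new_vals
        times = np.concatenate([[beats.times[0]], beats.times[0] + np.cumsum(ibis)])
        new_flags = np.where(flags == FLAGGED, CORRECTED, flags)
        out = BeatTimes(times=times, flags=new_flags, source=beats.source)
    else:  # merge_split
        clean_ibi = np.setdiff1d(np.arange(ibis.size), flagged_ibi_idx)
        if clean_ibi.size == 0:
            raise QualityError("no clean IBIs left to anchor on")
        local_mean = float(np.mean(ibis[clean_ibi]))
        times_out: list[float] = []
        flags_out: list[str] = []
        i = 0
        flagged_set = set(int(j) for j in flagged_beats)
        times_out.append(float(beats.times[0]))
        flags_out.append(str(flags[0]))
        while i + 1 < len(beats):
            j = i + 1
            if j not in flagged_set:
                times_out.append(float(beats.times[j]))
                flags_out.append(str(flags[j]))
                i = j
                continue
            # run of flagged beats: find next clean anchor
            k = j
            while k < len(beats) and int(k) in flagged_set:
                k += 1
            if k >= len(beats):  # run hits the end: keep last beat as anchor
                k = len(beats) - 1
            t_a, t_b = float(beats.times[i]), float(beats.times[k])
            n_sub = max(int(round((t_b - t_a) / local_mean)), 1)
            inner = t_a + (t_b - t_a) * np.arange(1, n_sub) / n_sub
            log.append(
                f"gap {t_a:.3f}-{t_b:.3f}s: {k - i} interval(s) -> {n_sub} interval(s), "
                f"{inner.size} beat(s) redistributed"
            )
            for t in inner:
                times_out.append(float(t))
                flags_out.append(CORRECTED)
            times_out.append(t_b)
            flags_out.append(CORRECTED if int(k) in flagged_set else str(flags[k]))
            i = k
        out = BeatTimes(
            times=np.asarray(times_out),
            flags=np.asarray(flags_out, dtype=object),
            source=beats.source,
        )

    if np.any(out.ibis <= 0.25):
        log.append("WARNING: corrected series still contains IBIs <= 0.25 s")
    return out, log
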