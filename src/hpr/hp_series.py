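"""Heart-period time series: interpolation, filtering, trial epochs.

Beat times are converted to a continuous heart-period signal by
assigning each interbeat interval (in ms) to its *following* beat and
interpolating linearly on a uniform grid (10 Hz by default). The
series is band-pass filtered with a bidirectional (zero-phase)
Butterworth filter, then cut into 11 s trial epochs baseline-corrected
against the 5 s preceding CS onset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .beat_detect import BeatTimes
from .exceptions import InsufficientDataError, InvalidSpecError, ValidationError

__all__ = [
    "FilterSpec",
    "HeartPeriodSeries",
    "TrialEpoch",
    "beats_to_hp",
    "bandpass",
    "apply_filter",
    "epoch_trials",
    "EPOCH_WINDOW_S",
    "BASELINE_WINDOW_S",
]

logger = logging.getLogger(__name__)

#: trial epoch window relative to CS onset, half-open [0, 11) s
EPOCH_WINDOW_S = (0.0, 11.0)
#: baseline window relative to CS onset, half-open [-5, 0) s
BASELINE_WINDOW_S = (-5.0, 0.0)


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification for the bidirectional Butterworth filter.

    ``order_per_pass`` is the order of each directional pass; the
    effective order of the zero-phase filter is twice that.
    """

    hp_cutoff: float = 0.015
    lp_cutoff: float = 0.5
    order_per_pass: int = 2
    direction: str = "bidirectional"

    def __post_init__(self) -> None:
        if not (0 < self.hp_cutoff < self.lp_cutoff):
            raise InvalidSpecError(
                f"need 0 < hp_cutoff < lp_cutoff, got ({self.hp_cutoff}, {self.lp_cutoff})"
            )
        if self.order_per_pass < 1:
            raise InvalidSpecError("order_per_pass must be >= 1")


@dataclass(frozen=True)
class HeartPeriodSeries:
    """Uniformly sampled heart-period signal in ms."""

    values: np.ndarray
    fs: float
    t0: float = 0.0
    filter_spec: FilterSpec | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if not np.all(np.isfinite(values)):
            raise ValidationError("series contains non-finite values")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class TrialEpoch:
    """Baseline-corrected heart period (ms) on the [0, 11) s grid from CS onset."""

    values: np.ndarray
    fs: float
    condition: str
    reinforced: bool
    soa: float
    onset: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.fs


def beats_to_hp(beats: BeatTimes, fs_out: float = 10.0) -> HeartPeriodSeries:
    """Interpolate interbeat intervals to a uniform heart-period series.

    Each IBI (ms) is attached at the time of the later beat of its
    pair; values between attachment points are linearly interpolated,
    and held at the nearest attachment value before the first / after
    the last point. The grid starts at the first beat.
    """
    if len(beats) < 2:
        raise InsufficientDataError("need at least 2 beats to form an IBI series")
    t0 = float(beats.times[0])
    n = int(np.floor((beats.times[-1] - t0) * fs_out + 1e-9)) + 1
    grid = t0 + np.arange(n) / fs_out
    attach_t = beats.times[1:]
    attach_v = beats.ibis * 1000.0  # ms
    values = np.interp(grid, attach_t, attach_v)
    return HeartPeriodSeries(values=values, fs=fs_out, t0=t0)


def apply_filter(values: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a raw value array."""
    nyq = fs / 2.0
    if spec.lp_cutoff >= nyq:
        raise InvalidSpecError(f"lp_cutoff {spec.lp_cutoff} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(
        spec.order_per_pass,
        [spec.hp_cutoff, spec.lp_cutoff],
        btype="band",
        fs=fs,
        output="sos",
    )
    return sps.sosfiltfilt(sos, np.asarray(values, dtype=float))


def bandpass(
    series: HeartPeriodSeries, spec: FilterSpec, allow_refilter: bool = False
) -> HeartPeriodSeries:
    """Band-pass filter a heart-period series (forward + backward pass).

    The zero-phase output has no phase distortion and the DC component
    is removed. Refiltering an already-filtered series is refused
    unless ``allow_refilter`` is set.
    """
    if series.filter_spec is not None and not allow_refilter:
        raise InvalidSpecError("series already filtered; pass allow_refilter=True to refilter")
    filtered = apply_filter(series.values, spec, series.fs)
    return replace(series, values=filtered, filter_spec=spec)


def epoch_trials(
    series: HeartPeriodSeries,
    trials: pd.DataFrame,
    window: tuple[float, float] = EPOCH_WINDOW_S,
    baseline: tuple[float, float] = BASELINE_WINDOW_S,
) -> list[TrialEpoch]:
    """Cut baseline-corrected trial epochs from a heart-period series.

    One epoch per trial whose full ``[onset + baseline[0], onset +
    window[1])`` span lies inside the recording; out-of-bounds trials
    are dropped with a logged warning. The mean over the baseline
    window is subtracted, so the pre-CS mean maps to 0.
    """
    fs = series.fs
    n_win = int(round((window[1] - window[0]) * fs))
    n_base = int(round((baseline[1] - baseline[0]) * fs))
    epochs: list[TrialEpoch] = []
    for row in trials.itertuples(index=False):
        onset = float(row.onset)
        i_on = int(round((onset + window[0] - series.t0) * fs))
        i_base = int(round((onset + baseline[0] - series.t0) * fs))
        if i_base < 0 or i_on + n_win > len(series):
            logger.warning(
                "trial at onset %.2fs exceeds recording bounds; dropped", onset
            )
            continue
        base_mean = float(np.mean(series.values[i_base : i_base + n_base]))
        vals = series.values[i_on : i_on + n_win] - base_mean
        epochs.append(
            TrialEpoch(
                values=vals,
                fs=fs,
                condition=str(row.trial_type),
                reinforced=bool(getattr(row, "reinforced", False)),
                soa=float(getattr(row, "soa", 3.5)),
                onset=onset,
            )
        )
    return epochs
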