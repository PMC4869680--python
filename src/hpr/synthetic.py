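"""Ground-truthed synthetic fear-conditioning sessions.

The generator emulates the statistical structure the convolution model
assumes: an instantaneous heart-period function

    p(t) = mean_hp + RSA sinusoid + slow drift
           + sum over trials of amp * canonical_shape(t - lock time - jitter)

(ms), from which beats are drawn so that each interbeat interval
equals p evaluated at the beat (a first-order integrate-and-fire
inversion of the interpolation performed downstream), plus white
per-beat noise. Trial schedules follow the conditioning designs the
model targets: intertrial intervals drawn from {7, 9, 11} s, 50%
reinforcement of CS+, SOA 3.5 s (delay) or 4 s (trace).

Respiratory sinus arrhythmia is modelled as a fixed-frequency sinusoid
(default 0.25 Hz) with random phase per subject — real RSA is
broadband, but it enters the model only as nuisance variance, so a
narrowband surrogate suffices for testing. Conditioned responses are
injected with the canonical gamma shape itself plus per-subject
latency jitter: the self-consistency regime in which the derivative
component of model G2 should demonstrably help.

Raw-waveform renderers (:func:`render_ecg`, :func:`render_pps`)
exercise the beat detectors with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .basis import CANONICAL_PARAMS, DEFAULT_PARAMS_NAME, REFERENCE_SOA, gamma_rf
from .beat_detect import BeatTimes
from .exceptions import ConfigError

__all__ = [
    "SimConfig",
    "GroundTruth",
    "Session",
    "simulate_session",
    "simulate_study",
    "render_ecg",
    "render_pps",
    "fixture_curve",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation settings.

    Defaults reproduce the delay-conditioning design the model was
    built for: 80 CS+ (half reinforced, so 40 retained) and 40 CS− per
    subject, SOA 3.5 s, ITIs drawn from {7, 9, 11} s. Response
    amplitudes default to a 40 ms CS+ and 10 ms CS− bradycardia
    (a 30 ms conditioned difference) against a 40 ms RSA oscillation,
    with 0.5 s between-subject latency jitter.
    """

    n_subjects: int = 30
    n_cs_plus: int = 80
    n_cs_minus: int = 40
    reinforcement_rate: float = 0.5
    soa: float = 3.5
    cs_duration: float = 4.0
    iti_choices: tuple[float, ...] = (7.0, 9.0, 11.0)
    mean_hp: float = 900.0  # ms
    rsa_freq: float = 0.25  # Hz
    rsa_amp: float = 40.0  # ms
    drift_amp: float = 30.0  # ms
    drift_freq: float = 0.005  # Hz
    resp_amp_cs_plus: float = 40.0  # ms
    resp_amp_cs_minus: float = 10.0  # ms
    us_resp_amp: float = 50.0  # ms, response evoked by the actual US
    latency_jitter_sd: float = 0.5  # s, between subjects
    lock: str = "cs"
    noise_sd: float = 10.0  # ms, white per-beat noise
    lead_in: float = 30.0  # s of recording before the first CS
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.lock not in ("cs", "us"):
            raise ConfigError(f"lock must be 'cs' or 'us', got {self.lock!r}")
        if not (0.0 <= self.reinforcement_rate <= 1.0):
            raise ConfigError("reinforcement_rate must be in [0, 1]")
        if self.mean_hp <= 300:
            raise ConfigError("mean_hp must exceed 300 ms")


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    trial_amps: np.ndarray  # ms, one per trial (CS response)
    latency_shift: float  # s, subject-level jitter
    rsa_phase: float
    drift_phase: float
    beat_times: np.ndarray
    hp_fn_components: dict = field(repr=False, default_factory=dict)


@dataclass(frozen=True)
class Session:
    subject_id: str
    beats: BeatTimes
    trials: pd.DataFrame
    truth: GroundTruth


# canonical shape lookup shared by all sessions (peak-normalized, 100 Hz)
_SHAPE_FS = 100.0
_SHAPE = gamma_rf(CANONICAL_PARAMS[DEFAULT_PARAMS_NAME], fs=_SHAPE_FS, duration=11.0).samples
_SHAPE_T = np.arange(_SHAPE.size) / _SHAPE_FS


def _canonical_shape(t: np.ndarray | float) -> np.ndarray | float:
    """Peak-normalized canonical response shape, zero outside [0, 11) s."""
    return np.interp(t, _SHAPE_T, _SHAPE, left=0.0, right=0.0)


def _make_schedule(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_cs_plus + cfg.n_cs_minus
    types = np.array(["cs_plus"] * cfg.n_cs_plus + ["cs_minus"] * cfg.n_cs_minus)
    rng.shuffle(types)
    itis = rng.choice(cfg.iti_choices, size=n)
    onsets = cfg.lead_in + np.concatenate([[0.0], np.cumsum(cfg.cs_duration + itis[:-1])])
    reinforced = np.zeros(n, dtype=int)
    plus_idx = np.flatnonzero(types == "cs_plus")
    n_reinf = int(round(cfg.reinforcement_rate * plus_idx.size))
    reinforced[rng.choice(plus_idx, size=n_reinf, replace=False)] = 1
    return pd.DataFrame(
        {
            "onset": onsets,
            "duration": cfg.cs_duration,
            "trial_type": types,
            "reinforced": reinforced,
            "soa": cfg.soa,
        }
    )


def simulate_session(cfg: SimConfig, rng: np.random.Generator | int | None = None,
                     subject_id: str = "sub-01") -> Session:
    """Simulate one subject's session: beats, trial table, ground truth."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng if rng is not None else cfg.seed)
    trials = _make_schedule(cfg, rng)

    latency = float(rng.normal(0.0, cfg.latency_jitter_sd))
    rsa_phase = float(rng.uniform(0, 2 * np.pi))
    drift_phase = float(rng.uniform(0, 2 * np.pi))

    lock_shift = (cfg.soa - REFERENCE_SOA) if cfg.lock == "us" else 0.0
    onsets = trials["onset"].to_numpy()
    is_plus = (trials["trial_type"] == "cs_plus").to_numpy()
    reinforced = trials["reinforced"].to_numpy().astype(bool)
    trial_amps = np.where(is_plus, cfg.resp_amp_cs_plus, cfg.resp_amp_cs_minus).astype(float)
    resp_onsets = onsets + lock_shift + latency
    us_onsets = onsets[reinforced] + trials.loc[reinforced, "soa"].to_numpy()

    # event times sorted for a cheap "active responses" lookup
    ev_t = np.concatenate([resp_onsets, us_onsets])
    ev_a = np.concatenate([trial_amps, np.full(us_onsets.size, cfg.us_resp_amp)])
    order = np.argsort(ev_t)
    ev_t, ev_a = ev_t[order], ev_a[order]

    w_rsa = 2 * np.pi * cfg.rsa_freq
    w_drift = 2 * np.pi * cfg.drift_freq

    def p_of_t(t: float) -> float:
        val = (
            cfg.mean_hp
            + cfg.rsa_amp * np.sin(w_rsa * t + rsa_phase)
            + cfg.drift_amp * np.sin(w_drift * t + drift_phase)
        )
        # responses active at t: event onsets within (t - 11, t]
        lo = np.searchsorted(ev_t, t - 11.0)
        hi = np.searchsorted(ev_t, t, side="right")
        if hi > lo:
            val += float(np.sum(ev_a[lo:hi] * _canonical_shape(t - ev_t[lo:hi])))
        return val

    # renewal process: the IBI ending at beat t_{k+1} equals p(t_{k+1}),
    # the convention the downstream interpolation inverts. The implicit
    # equation t_{k+1} = t_k + p(t_{k+1})/1000 is solved by fixed-point
    # iteration (p varies slowly relative to one beat).
    t_end = float(onsets[-1]) + 16.0
    noise = rng.normal(0.0, cfg.noise_sd, size=int(t_end / 0.3) + 16)
    times = []
    t = 0.0
    i = 0
    while t < t_end:
        times.append(t)
        t_next = t + p_of_t(t) / 1000.0
        for _ in range(3):
            t_next = t + (p_of_t(t_next) + noise[i]) / 1000.0
        ibi = t_next - t
        if ibi <= 0.25:
            raise ConfigError(
                f"instantaneous heart period {ibi * 1000:.0f} ms <= 250 ms at t={t:.1f}s; "
                "reduce amplitudes or noise"
            )
        t = t_next
        i += 1
    beat_times = np.asarray(times)

    truth = GroundTruth(
        trial_amps=trial_amps,
        latency_shift=latency,
        rsa_phase=rsa_phase,
        drift_phase=drift_phase,
        beat_times=beat_times,
        hp_fn_components={"p_of_t": p_of_t, "lock_shift": lock_shift},
    )
    return Session(
        subject_id=subject_id,
        beats=BeatTimes(times=beat_times, source="ecg"),
        trials=trials,
        truth=truth,
    )


def simulate_study(cfg: SimConfig) -> list[Session]:
    """Simulate ``cfg.n_subjects`` independent sessions, seeded reproducibly."""
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_subjects)
    return [
        simulate_session(cfg, np.random.default_rng(child), subject_id=f"sub-{i + 1:02d}")
        for i, child in enumerate(children)
    ]


# ---------------------------------------------------------------------------
# raw waveform rendering
# ---------------------------------------------------------------------------

# PQRST wave parameters: (offset s, amplitude, width s)
_ECG_WAVES = (
    (-0.20, 0.15, 0.025),  # P
    (-0.025, -0.10, 0.010),  # Q
    (0.0, 1.00, 0.012),  # R
    (0.025, -0.15, 0.010),  # S
    (0.25, 0.30, 0.060),  # T
)


def _add_noise(x: np.ndarray, snr_db: float | None, rng: np.random.Generator) -> np.ndarray:
    if snr_db is None:
        return x
    rms = float(np.sqrt(np.mean(x**2)))
    if rms == 0:
        rms = 1.0
    sigma = rms / (10.0 ** (snr_db / 20.0))
    return x + rng.normal(0.0, sigma, size=x.size)


def render_ecg(beats: BeatTimes, fs: float = 500.0, snr_db: float | None = None,
               seed: int | None = None, duration: float | None = None):
    """Render a synthetic ECG with a PQRST complex at each beat.

    An empty beat list yields pure noise. ``snr_db`` sets additive
    white noise relative to the rendered signal RMS; ``None`` disables
    it.
    """
    from .beat_detect import Waveform

    if fs < 250:
        raise ConfigError("render_ecg needs fs >= 250 Hz")
    rng = np.random.default_rng(seed)
    if duration is None:
        duration = (float(beats.times[-1]) + 1.0) if len(beats) else 10.0
    n = int(round(duration * fs))
    x = np.zeros(n)
    tmpl_t = np.arange(-0.3, 0.45, 1.0 / fs)
    tmpl = np.zeros(tmpl_t.size)
    for off, amp, width in _ECG_WAVES:
        tmpl += amp * np.exp(-0.5 * ((tmpl_t - off) / width) ** 2)
    start_off = int(round(0.3 * fs))
    for bt in beats.times:
        i0 = int(round(bt * fs)) - start_off
        lo, hi = max(i0, 0), min(i0 + tmpl.size, n)
        if hi > lo:
            x[lo:hi] += tmpl[lo - i0 : hi - i0]
    return Waveform(samples=_add_noise(x, snr_db, rng), fs=fs, modality="ecg")


def render_pps(beats: BeatTimes, fs: float = 100.0, snr_db: float | None = None,
               lag: float = 0.2, seed: int | None = None, duration: float | None = None):
    """Render a peripheral-pulse waveform: a smooth pulse at each beat + lag.

    The pulse-transit ``lag`` shifts every pulse identically, so it
    cancels in interbeat intervals and is irrelevant downstream.
    """
    from .beat_detect import Waveform

    if fs < 100:
        raise ConfigError("render_pps needs fs >= 100 Hz")
    rng = np.random.default_rng(seed)
    if duration is None:
        duration = (float(beats.times[-1]) + lag + 1.0) if len(beats) else 10.0
    n = int(round(duration * fs))
    x = np.zeros(n)
    tau = 0.08
    tmpl_t = np.arange(0.0, 0.6, 1.0 / fs)
    tmpl = (tmpl_t / tau) ** 2 * np.exp(-tmpl_t / tau)
    tmpl /= tmpl.max()
    for bt in beats.times:
        i0 = int(round((bt + lag) * fs))
        lo, hi = max(i0, 0), min(i0 + tmpl.size, n)
        if hi > lo:
            x[lo:hi] += tmpl[lo - i0 : hi - i0]
    return Waveform(samples=_add_noise(x, snr_db, rng), fs=fs, modality="pps")


# ---------------------------------------------------------------------------
# fixture component curves (synthetic stand-ins)
# ---------------------------------------------------------------------------


def fixture_curve(kind: str, fs: float = 10.0, duration: float = 11.0) -> np.ndarray:
    """Generate the synthetic stand-in component curves shipped as fixtures.

    ``early`` is a biphasic early stimulus-processing response peaking
    well before the conditioned bradycardia; ``cs_minus_baseline`` is
    a triphasic deceleration-acceleration-deceleration CS− mean
    response; ``brief_stimulus`` is an early-peaking response to brief
    stimuli used as the prior for autonomic-input reconstruction. All
    are invented, plausible shapes (peak-normalized), not estimates
    from any dataset.
    """
    from scipy.stats import gamma as gd

    x = np.arange(int(round(duration * fs))) / fs
    if kind == "early":
        y = gd.pdf(x, 3.0, scale=0.25) - 0.7 * gd.pdf(x, 4.0, scale=0.45)
    elif kind == "cs_minus_baseline":
        y = (
            0.6 * gd.pdf(x, 4.0, scale=0.30)
            - 0.5 * gd.pdf(x, 6.0, scale=0.45)
            + 1.2 * gd.pdf(x, 25.0, scale=0.21)
        )
    elif kind == "brief_stimulus":
        y = gd.pdf(x, 4.0, scale=0.33)
    else:
        raise ConfigError(f"unknown fixture kind {kind!r}")
    return y / np.max(np.abs(y))
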