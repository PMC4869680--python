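"""Convolution GLM: design construction, inversion, condition scoring.

The heart-period series Y is modelled as Y = X·beta + noise, where each
column of X is a train of impulses at the onsets of one input type
convolved with one basis-set component, filtered identically to the
data. beta is obtained with the Moore–Penrose pseudoinverse, i.e. the
minimum-norm least-squares solution.

Model-based condition scores reconstruct the estimated response from
the entire basis set and take the signed maximal variation from
baseline between 2 and 11 s after CS onset. Model-free scorers P1-P3
apply classical peak-scoring statistics to the condition-mean epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import BasisSet
from .exceptions import MissingConditionError, ValidationError
from .hp_series import FilterSpec, HeartPeriodSeries, TrialEpoch, apply_filter

__all__ = [
    "DesignMatrix",
    "AmplitudeEstimates",
    "build_design",
    "convolve_impulses",
    "estimate",
    "reconstruct_response",
    "score_model_based",
    "score_model_free",
    "condition_mean_epoch",
    "SCORE_WINDOW_S",
    "P3_WINDOW_S",
]

#: scoring window for P1/P2 and model-based scores (s after CS onset)
SCORE_WINDOW_S = (2.0, 11.0)
#: averaging window for P3 (s after CS onset)
P3_WINDOW_S = (2.0, 8.0)

CONDITIONS = ("cs_plus", "cs_minus")


@dataclass(frozen=True)
class DesignMatrix:
    X: np.ndarray
    column_meta: tuple[tuple[str, str], ...]  # (condition, basis kind)
    fs: float

    @property
    def n_samples(self) -> int:
        return int(self.X.shape[0])


@dataclass(frozen=True)
class AmplitudeEstimates:
    """GLM amplitude estimates, one per design column (ms per unit input)."""

    beta: np.ndarray
    column_meta: tuple[tuple[str, str], ...]
    model_id: str
    subject_id: str | None = None


def convolve_impulses(onset_indices: np.ndarray, h: np.ndarray, n_samples: int) -> np.ndarray:
    """Convolve a unit impulse train with a sampled response function.

    Equivalent to summing shifted copies of ``h`` at every onset;
    contributions past the end of the series are truncated.
    """
    imp = np.zeros(n_samples)
    idx = np.asarray(onset_indices, dtype=int)
    keep = (idx >= 0) & (idx < n_samples)
    np.add.at(imp, idx[keep], 1.0)
    return np.convolve(imp, h)[:n_samples]


def build_design(
    trials: pd.DataFrame,
    bset: BasisSet,
    n_samples: int,
    fs: float,
    t0: float = 0.0,
    filter_spec: FilterSpec | None = None,
    nuisance_reinforced: bool = True,
) -> DesignMatrix:
    """Build the convolution design matrix for one subject's session.

    Per condition (retained CS+ / CS−) and basis function, one column:
    the impulse train at that condition's CS onsets convolved with the
    basis component. With a US-locked basis set the shifted component
    samples place the response relative to the nominal US time.

    Reinforced CS+ trials are excluded from the condition columns but —
    by default — modelled as separate nuisance regressors (the
    canonical component at their CS onset plus a US-evoked regressor at
    the actual US time), so their variance does not bleed into the
    retained-trial estimates.

    When ``filter_spec`` is given each column is band-pass filtered
    identically to the data.
    """
    if bset.lock == "us" and trials["soa"].nunique() > 1:
        raise ValidationError("US-locked design requires a constant SOA per session")
    reinforced = trials.get("reinforced", pd.Series(0, index=trials.index)).astype(bool)
    onset_idx = np.round((trials["onset"].to_numpy(dtype=float) - t0) * fs).astype(int)

    cols: list[np.ndarray] = []
    meta: list[tuple[str, str]] = []
    for cond in CONDITIONS:
        mask = (trials["trial_type"] == cond).to_numpy() & ~reinforced.to_numpy()
        if not mask.any():
            continue
        for f in bset.functions:
            cols.append(convolve_impulses(onset_idx[mask], f.samples, n_samples))
            meta.append((cond, f.kind))
    if nuisance_reinforced and reinforced.any():
        r_mask = (trials["trial_type"] == "cs_plus").to_numpy() & reinforced.to_numpy()
        if r_mask.any():
            canonical = next(f for f in bset.functions if f.kind == "canonical")
            cols.append(convolve_impulses(onset_idx[r_mask], canonical.samples, n_samples))
            meta.append(("nuisance_reinforced", "canonical"))
            soa = trials.loc[r_mask, "soa"].to_numpy(dtype=float) if "soa" in trials else np.full(r_mask.sum(), 3.5)
            us_idx = np.round((trials.loc[r_mask, "onset"].to_numpy(dtype=float) + soa - t0) * fs).astype(int)
            cols.append(convolve_impulses(us_idx, canonical.samples, n_samples))
            meta.append(("nuisance_us", "canonical"))
    if not cols:
        raise MissingConditionError("no retained trials to build a design from")
    X = np.column_stack(cols)
    if filter_spec is not None:
        X = np.column_stack([apply_filter(c, filter_spec, fs) for c in X.T])
    return DesignMatrix(X=X, column_meta=tuple(meta), fs=fs)


def estimate(design: DesignMatrix, data: HeartPeriodSeries | np.ndarray,
             model_id: str = "", subject_id: str | None = None) -> AmplitudeEstimates:
    """Invert the GLM: beta = pinv(X) · Y (minimum-norm least squares)."""
    y = data.values if isinstance(data, HeartPeriodSeries) else np.asarray(data, dtype=float)
    if y.size != design.n_samples:
        raise ValidationError(f"data length {y.size} != design rows {design.n_samples}")
    if not np.all(np.isfinite(y)):
        raise ValidationError("data contain non-finite values")
    beta = np.linalg.pinv(design.X) @ y
    return AmplitudeEstimates(beta=beta, column_meta=design.column_meta,
                              model_id=model_id, subject_id=subject_id)


def reconstruct_response(est: AmplitudeEstimates, bset: BasisSet, condition: str) -> np.ndarray:
    """Reconstruct the estimated response of one condition from the full basis set."""
    out = np.zeros(bset.functions[0].samples.size)
    found = False
    for (cond, kind), b in zip(est.column_meta, est.beta):
        if cond != condition:
            continue
        f = next(f for f in bset.functions if f.kind == kind)
        out = out + b * f.samples
        found = True
    if not found:
        raise MissingConditionError(f"no columns for condition {condition!r}")
    return out


def _signed_extremum(values: np.ndarray) -> float:
    """Value at the (earliest) maximum of |values|, sign preserved."""
    i = int(np.argmax(np.abs(values)))  # argmax returns the first maximal index
    return float(values[i])


def _window_slice(fs: float, window: tuple[float, float]) -> slice:
    return slice(int(np.ceil(window[0] * fs)), int(np.ceil(window[1] * fs)))


def score_model_based(
    est: AmplitudeEstimates,
    bset: BasisSet,
    window: tuple[float, float] = SCORE_WINDOW_S,
) -> dict[str, float]:
    """Signed maximal variation from baseline of the reconstructed response.

    Reconstructs each condition's response from the entire basis set
    and scores the value at the time of maximum absolute deviation
    within ``window``; equal-magnitude ties break to the earliest
    sample.
    """
    sl = _window_slice(bset.fs, window)
    scores: dict[str, float] = {}
    for cond in CONDITIONS:
        if any(c == cond for c, _ in est.column_meta):
            scores[cond] = _signed_extremum(reconstruct_response(est, bset, cond)[sl])
    return scores


def condition_mean_epoch(epochs: list[TrialEpoch], condition: str) -> np.ndarray:
    """Mean epoch over a condition's retained (non-reinforced) trials."""
    vals = [e.values for e in epochs if e.condition == condition and not e.reinforced]
    if not vals:
        raise MissingConditionError(f"no retained epochs for condition {condition!r}")
    return np.mean(vals, axis=0)


def score_model_free(epochs: list[TrialEpoch], method: str) -> dict[str, float]:
    """Classical peak-scoring of the condition-mean epoch.

    P1: signed amplitude of the maximal variation from baseline in
    [2, 11) s. P2: maximum positive peak in [2, 11) s. P3: average
    response in [2, 8) s (shorter window: the mean is more sensitive
    to noise after the response ends).
    """
    if method not in ("P1", "P2", "P3"):
        raise ValidationError(f"unknown model-free method {method!r}")
    scores: dict[str, float] = {}
    for cond in CONDITIONS:
        mean_epoch = condition_mean_epoch(epochs, cond)
        fs = epochs[0].fs
        if method == "P1":
            scores[cond] = _signed_extremum(mean_epoch[_window_slice(fs, SCORE_WINDOW_S)])
        elif method == "P2":
            scores[cond] = float(np.max(mean_epoch[_window_slice(fs, SCORE_WINDOW_S)]))
        else:
            scores[cond] = float(np.mean(mean_epoch[_window_slice(fs, P3_WINDOW_S)]))
    return scores
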