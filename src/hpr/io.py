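"""File readers and writers: events tables, beat lists, series, scores.

Formats are deliberately plain: beat lists are one timestamp (seconds,
6 decimals) per line with flags in a companion TSV; trial tables use a
BIDS-events-like TSV dialect; series and scores are CSV/TSV. Times are
written with fixed 6-decimal formatting so write→read round trips are
bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .beat_detect import CLEAN, BeatTimes, Waveform
from .exceptions import ValidationError
from .hp_series import HeartPeriodSeries

__all__ = [
    "read_events",
    "write_events",
    "read_beats",
    "write_beats",
    "read_waveform_csv",
    "write_waveform_csv",
    "write_series",
    "read_series",
    "write_scores",
    "read_scores",
    "write_evidence",
]

TRIAL_TYPES = ("cs_plus", "cs_minus")
EVENT_DEFAULTS = {"duration": 4.0, "reinforced": 0, "soa": 3.5}


def read_events(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial events table (TSV).

    Required columns: ``onset`` (s), ``trial_type``; optional
    ``duration``, ``reinforced``, ``soa`` get defaults. Onsets must be
    strictly increasing and every trial_type must be ``cs_plus`` or
    ``cs_minus``.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"onset", "trial_type"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {sorted(missing)}")
    for col, default in EVENT_DEFAULTS.items():
        if col not in df.columns:
            df[col] = default
    bad = df.loc[~df["trial_type"].isin(TRIAL_TYPES)]
    if not bad.empty:
        raise ValidationError(
            f"{path}: unknown trial_type in row(s) {list(bad.index)}: "
            f"{sorted(bad['trial_type'].unique())}"
        )
    onsets = df["onset"].to_numpy(dtype=float)
    if onsets.size >= 2 and not np.all(np.diff(onsets) > 0):
        raise ValidationError(f"{path}: onsets must be strictly increasing")
    return df[["onset", "duration", "trial_type", "reinforced", "soa"]]


def write_events(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_beats(beats: BeatTimes, path: str | Path, flags_path: str | Path | None = None) -> None:
    """One timestamp per line; flags (time, flag) to a companion TSV."""
    path = Path(path)
    path.write_text("".join(f"{t:.6f}\n" for t in beats.times))
    if flags_path is not None:
        with open(flags_path, "w") as fh:
            fh.write("time\tflag\n")
            for t, f in zip(beats.times, beats.flags):
                fh.write(f"{t:.6f}\t{f}\n")


def read_beats(path: str | Path, flags_path: str | Path | None = None,
               source: str = "file") -> BeatTimes:
    times = np.array([float(line) for line in Path(path).read_text().split()])
    flags = None
    if flags_path is not None:
        tbl = pd.read_csv(flags_path, sep="\t")
        flags = tbl["flag"].to_numpy(dtype=object)
    return BeatTimes(times=times, flags=flags, source=source)


def read_waveform_csv(path: str | Path, sidecar: str | Path | None = None) -> Waveform:
    """Read a single-channel waveform (one sample per line) + JSON sidecar.

    The sidecar (default: same stem + ``.json``) must provide ``fs``
    and ``modality``; ``t0`` defaults to 0.
    """
    path = Path(path)
    if sidecar is None:
        sidecar = path.with_suffix(".json")
    meta = json.loads(Path(sidecar).read_text())
    if "fs" not in meta or "modality" not in meta:
        raise ValidationError(f"{sidecar}: sidecar must define fs and modality")
    samples = np.loadtxt(path, dtype=float, ndmin=1)
    return Waveform(samples=samples, fs=float(meta["fs"]),
                    modality=str(meta["modality"]), t0=float(meta.get("t0", 0.0)))


def write_waveform_csv(wave: Waveform, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, wave.samples, fmt="%.8f")
    sidecar = {"fs": wave.fs, "modality": wave.modality, "t0": wave.t0}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def write_series(series: HeartPeriodSeries, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("time,hp_ms\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{t:.6f},{v:.6f}\n")


def read_series(path: str | Path) -> HeartPeriodSeries:
    df = pd.read_csv(path)
    t = df["time"].to_numpy(dtype=float)
    fs = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 10.0
    return HeartPeriodSeries(values=df["hp_ms"].to_numpy(dtype=float),
                             fs=float(round(fs, 6)), t0=float(t[0]))


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    """Scores TSV with columns subject, condition, method, score_ms."""
    out = scores.rename(columns={"score": "score_ms"})
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.rename(columns={"score_ms": "score"})


def write_evidence(evidence: dict, path: str | Path) -> None:
    """Evidence report JSON: per-method nll/t/p/n plus comparisons."""
    Path(path).write_text(json.dumps(evidence, indent=1, sort_keys=True))
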