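"""Reading, resampling and windowing of intracranial-EEG epochs.

This module owns the pre-processing conventions used throughout the
package:

* epochs are either *interictal* (baseline, nominally 300 s) or *ictal*
  (58 s spanning -30 s to +28 s around electrical seizure onset);
* every recording is brought to a common rate of 256 Hz by polyphase
  antialiasing resampling — no other filtering or artefact removal is
  applied anywhere;
* features are computed in 2-s non-overlapping windows (512 samples at
  256 Hz).  A 300-s interictal epoch yields 150 windows; an ictal epoch
  yields 14 retained pre-onset and 14 post-onset windows;
* post-onset ictal feature values are normalised against the pre-onset
  baseline, and interictal feature series are temporally resampled from
  ~150 to 28 samples so the two epoch types contribute comparable
  observation counts.

All sample intervals are half-open ``[start, end)`` and 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

COMMON_RATE_HZ = 256
WINDOW_LENGTH_S = 2.0
ICTAL_DURATION_S = 58.0
ICTAL_ONSET_S = 30.0
N_RETAINED_PRE = 14
N_RETAINED_POST = 14
INTERICTAL_SERIES_LEN = 28

INTERICTAL = "interictal"
ICTAL = "ictal"


class FormatError(ValueError):
    """A cohort file is missing, malformed, or inconsistent with its metadata."""


# ---------------------------------------------------------------------------
# Recording container
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """One epoch of multichannel iEEG.

    ``signal`` is channels x samples (arbitrary units).  ``onset_sample``
    is present iff the epoch is ictal and marks electrical seizure onset
    (+30 s from epoch start by construction).
    """

    signal: np.ndarray
    rate_hz: float
    epoch_type: str
    channel_names: list[str]
    patient_id: str
    recording_id: str
    onset_sample: int | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise FormatError("signal must be a channels x samples matrix")
        if np.isnan(self.signal).any():
            raise FormatError(f"recording {self.recording_id}: signal contains NaNs")
        if len(self.channel_names) != self.signal.shape[0]:
            raise FormatError(
                f"recording {self.recording_id}: {len(self.channel_names)} channel "
                f"names for {self.signal.shape[0]} signal rows"
            )
        if self.epoch_type not in (INTERICTAL, ICTAL):
            raise FormatError(f"unknown epoch_type {self.epoch_type!r}")
        if self.epoch_type == ICTAL and self.onset_sample is None:
            raise FormatError(
                f"recording {self.recording_id}: ictal epoch without onset_sample"
            )
        if self.epoch_type == INTERICTAL and self.onset_sample is not None:
            raise FormatError(
                f"recording {self.recording_id}: interictal epoch with onset_sample"
            )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


# ---------------------------------------------------------------------------
# Cohort directory I/O
#
# Layout (written by synthetic_cohort.write_cohort, readable for any
# ds004100-style export converted to the same shape):
#   sub-<ID>/
#     channels.tsv                      name, status, epileptogenic
#     <rec>_ieeg.bin + <rec>_ieeg.json  float32 channel-major + sidecar
#     (or <rec>_ieeg.tsv + .json        delimited-text fallback)
#     <rec>_events.tsv                  onset_sample (ictal only)
# ---------------------------------------------------------------------------


def _read_sidecar(path: Path) -> dict:
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    for key in ("rate_hz", "n_channels", "n_samples", "epoch_type"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar_path}: missing field {key!r}")
    return meta


def read_channels_tsv(path: Path) -> pd.DataFrame:
    """Read a BIDS-iEEG-style channels table (name, status, epileptogenic)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("name", "status", "epileptogenic"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    table["epileptogenic"] = table["epileptogenic"].str.lower().map(
        {"true": True, "false": False}
    )
    if table["epileptogenic"].isna().any():
        raise FormatError(f"{path}: epileptogenic column must be true/false")
    return table


def load_recording(path: str | Path, drop_bad: bool = True) -> Recording:
    """Load one recording from a cohort directory.

    ``path`` points at the signal container (``*_ieeg.bin`` or
    ``*_ieeg.tsv``); the JSON sidecar, the per-patient ``channels.tsv``
    and, for ictal epochs, the ``*_events.tsv`` file are located next to
    it.  Channels marked ``bad`` in channels.tsv are dropped before any
    computation when ``drop_bad`` is set.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing signal file {path}")
    meta = _read_sidecar(path)
    n_ch, n_samp = int(meta["n_channels"]), int(meta["n_samples"])

    if path.suffix == ".bin":
        raw = np.fromfile(path, dtype="<f4")
        if raw.size != n_ch * n_samp:
            raise FormatError(
                f"{path}: expected {n_ch * n_samp} float32 values, found {raw.size}"
            )
        sig = raw.reshape(n_ch, n_samp).astype(float)
    else:
        sig = np.loadtxt(path, delimiter="\t", ndmin=2)
        if sig.shape != (n_ch, n_samp):
            raise FormatError(
                f"{path}: sidecar shape ({n_ch}, {n_samp}) != data shape {sig.shape}"
            )

    channels_path = path.parent / "channels.tsv"
    if not channels_path.exists():
        raise FormatError(f"missing {channels_path}")
    channels = read_channels_tsv(channels_path)
    if len(channels) != n_ch:
        raise FormatError(
            f"{channels_path}: {len(channels)} channel rows for {n_ch} signal rows"
        )

    epoch_type = meta["epoch_type"]
    onset_sample = None
    if epoch_type == ICTAL:
        events_path = path.parent / (path.stem.replace("_ieeg", "") + "_events.tsv")
        if not events_path.exists():
            raise FormatError(f"missing events file {events_path} for ictal epoch")
        events = pd.read_csv(events_path, sep="\t")
        if "onset_sample" not in events.columns or events.empty:
            raise FormatError(f"{events_path}: missing onset_sample")
        onset_sample = int(events["onset_sample"].iloc[0])

    names = channels["name"].tolist()
    if drop_bad:
        good = (channels["status"] == "good").to_numpy()
        sig = sig[good]
        names = [n for n, g in zip(names, good) if g]

    return Recording(
        signal=sig,
        rate_hz=float(meta["rate_hz"]),
        epoch_type=epoch_type,
        channel_names=names,
        patient_id=str(meta.get("patient_id", path.parent.name)),
        recording_id=str(meta.get("recording_id", path.stem)),
        onset_sample=onset_sample,
    )


def write_recording(rec: Recording, path: str | Path, container: str = "bin") -> Path:
    """Write a recording plus sidecar; ``container`` is ``bin`` or ``tsv``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if container == "bin":
        out = path.with_suffix(".bin")
        rec.signal.astype("<f4").tofile(out)
    elif container == "tsv":
        out = path.with_suffix(".tsv")
        np.savetxt(out, rec.signal.astype("<f4"), delimiter="\t", fmt="%.7g")
    else:
        raise ValueError(f"unknown container {container!r}")
    meta = {
        "rate_hz": rec.rate_hz,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "epoch_type": rec.epoch_type,
        "patient_id": rec.patient_id,
        "recording_id": rec.recording_id,
    }
    if rec.onset_sample is not None:
        meta["onset_sample"] = int(rec.onset_sample)
    with open(out.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    return out


# ---------------------------------------------------------------------------
# Resampling to the common rate
# ---------------------------------------------------------------------------


def resample_to_common_rate(rec: Recording, target_hz: int = COMMON_RATE_HZ) -> Recording:
    """Bring a recording to the common rate by polyphase antialiasing resampling.

    The only signal conditioning in the pipeline: no additional filtering
    or artefact removal is applied.  A recording already at the target
    rate is returned unchanged.
    """
    if rec.rate_hz <= 0:
        raise ValueError("sampling rate must be positive")
    if rec.rate_hz == target_hz:
        return rec
    ratio = Fraction(target_hz, int(rec.rate_hz))
    resampled = sp_signal.resample_poly(
        rec.signal, ratio.numerator, ratio.denominator, axis=1
    )
    onset = rec.onset_sample
    if onset is not None:
        onset = int(round(onset * target_hz / rec.rate_hz))
    return replace(rec, signal=resampled, rate_hz=float(target_hz), onset_sample=onset)


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------


@dataclass
class WindowGrid:
    """Retained 2-s analysis windows for one recording.

    ``windows`` is a list of half-open ``(start, end)`` sample intervals.
    For ictal epochs ``tags`` marks each retained window ``pre`` or
    ``post`` (14 of each); for interictal epochs all tags are ``base``.
    """

    windows: list[tuple[int, int]]
    tags: list[str]
    window_samples: int
    epoch_type: str

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def indices(self, tag: str) -> list[int]:
        return [i for i, t in enumerate(self.tags) if t == tag]


def segment_windows(rec: Recording, drop_edge: str = "earliest") -> WindowGrid:
    """Partition a 256-Hz recording into non-overlapping 2-s windows.

    Interictal epochs keep every complete window (floor(duration / 2 s)).
    Ictal epochs span [-30 s, +28 s) around onset, i.e. 29 raw windows;
    to retain 14 pre- and 14 post-onset windows one pre-onset edge window
    is discarded: with ``drop_edge='earliest'`` (default) the window most
    distant from onset, [-30, -28); with ``'latest'`` the one adjacent to
    onset, [-2, 0).
    """
    if rec.rate_hz != COMMON_RATE_HZ:
        raise ValueError("segment_windows expects a recording at the common rate")
    win = int(round(WINDOW_LENGTH_S * rec.rate_hz))
    n_raw = rec.n_samples // win
    if n_raw < 1:
        raise ValueError(
            f"recording {rec.recording_id} shorter than one {WINDOW_LENGTH_S}-s window"
        )
    if rec.epoch_type == INTERICTAL:
        windows = [(i * win, (i + 1) * win) for i in range(n_raw)]
        return WindowGrid(windows, ["base"] * n_raw, win, INTERICTAL)

    onset = rec.onset_sample
    n_pre_raw = onset // win
    pre = [(onset - (i + 1) * win, onset - i * win) for i in reversed(range(n_pre_raw))]
    post = [
        (onset + i * win, onset + (i + 1) * win)
        for i in range((rec.n_samples - onset) // win)
    ]
    if len(pre) < N_RETAINED_PRE or len(post) < N_RETAINED_POST:
        raise ValueError(
            f"recording {rec.recording_id}: not enough windows around onset "
            f"({len(pre)} pre, {len(post)} post)"
        )
    if drop_edge == "earliest":
        pre = pre[-N_RETAINED_PRE:]
    elif drop_edge == "latest":
        pre = pre[len(pre) - N_RETAINED_PRE - 1 : -1] if len(pre) > N_RETAINED_PRE else pre
    else:
        raise ValueError(f"unknown drop_edge {drop_edge!r}")
    post = post[:N_RETAINED_POST]
    windows = pre + post
    tags = ["pre"] * len(pre) + ["post"] * len(post)
    return WindowGrid(windows, tags, win, ICTAL)


# ---------------------------------------------------------------------------
# Feature-series transforms
# ---------------------------------------------------------------------------


def normalize_postonset(pre: np.ndarray, post: np.ndarray) -> np.ndarray:
    """Normalise post-onset feature values against the pre-onset baseline.

    For each retained post-onset window::

        post_norm(w) = (post(w) - mean(pre)) / (mean(post) + mean(pre))

    Only the 14 normalised post-onset values enter downstream analysis;
    the pre-onset values themselves are not retained as observations.  A
    zero denominator (possible for signed features) yields NaN, flagged
    missing downstream.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.ndim != 1 or post.ndim != 1:
        raise ValueError("pre and post must be 1-D feature-value arrays")
    denom = np.nanmean(post) + np.nanmean(pre)
    if not np.isfinite(denom) or denom == 0:
        return np.full(post.shape, np.nan)
    return (post - np.nanmean(pre)) / denom


def resample_feature_series(
    values: np.ndarray,
    target_len: int = INTERICTAL_SERIES_LEN,
    method: str = "polyphase",
) -> np.ndarray:
    """Temporally downsample an interictal feature series to ``target_len``.

    Polyphase FIR (Kaiser-windowed lowpass) at the exact rational ratio,
    e.g. 150 -> 28 uses 14/75; a linear-interpolation fallback is
    available for cross-implementation checks.  NaNs are interpolated
    over before filtering (and the result is NaN-free) since the FIR
    would otherwise smear them.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < target_len:
        raise ValueError(f"series of length {n} shorter than target {target_len}")
    if n == target_len:
        return values.copy()
    nan_mask = np.isnan(values)
    if nan_mask.all():
        return np.full(target_len, np.nan)
    if nan_mask.any():
        idx = np.arange(n)
        values = values.copy()
        values[nan_mask] = np.interp(idx[nan_mask], idx[~nan_mask], values[~nan_mask])
    if method == "linear":
        return np.interp(
            np.linspace(0, n - 1, target_len), np.arange(n), values
        )
    ratio = Fraction(target_len, n)
    # padtype='line' avoids zero-padding edge transients; the high Kaiser
    # beta keeps passband ripple below 1e-7 so constant series survive.
    return sp_signal.resample_poly(
        values, ratio.numerator, ratio.denominator,
        padtype="line", window=("kaiser", 12.0),
    )


__all__ = [
    "COMMON_RATE_HZ",
    "WINDOW_LENGTH_S",
    "INTERICTAL",
    "ICTAL",
    "INTERICTAL_SERIES_LEN",
    "N_RETAINED_PRE",
    "N_RETAINED_POST",
    "FormatError",
    "Recording",
    "WindowGrid",
    "load_recording",
    "write_recording",
    "read_channels_tsv",
    "resample_to_common_rate",
    "segment_windows",
    "normalize_postonset",
    "resample_feature_series",
]
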