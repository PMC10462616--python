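"""Raw sEEG + behaviour -> normalized windowed theta/gamma power features.

Pipeline order is fixed and pinned by tests: linear detrend, zero-phase
Butterworth band-pass plus Hilbert envelope per band, one-second windows
with half-second hop (window means of power and of speed), then natural
log and per-column z-score across all windows of the session.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import fft, signal

from .simulate import BehavioralTrace, RecordingSession

__all__ = [
    "BandSpec",
    "WindowSpec",
    "FeatureTable",
    "THETA",
    "GAMMA",
    "DEFAULT_BANDS",
    "detrend_linear",
    "band_power",
    "window_features",
    "normalize_features",
    "extract_features",
]

log = logging.getLogger(__name__)

_LOG_EPS = 1e-12  # guard added before the log transform


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"need 0 < lo < hi, got ({self.lo}, {self.hi})")

    def validate_for(self, fs: float) -> None:
        if self.hi >= fs / 2.0:
            raise ValueError(
                f"band {self.name} upper edge {self.hi} Hz >= Nyquist {fs / 2.0} Hz"
            )


THETA = BandSpec("theta", 4.0, 8.0)
GAMMA = BandSpec("gamma", 52.0, 99.0)
DEFAULT_BANDS = (THETA, GAMMA)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding analysis window: length and hop in seconds."""

    length_s: float = 1.0
    hop_s: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.hop_s <= self.length_s:
            raise ValueError(
                f"need 0 < hop_s <= length_s, got ({self.hop_s}, {self.length_s})"
            )


@dataclass
class FeatureTable:
    """Window x (channel x band) power matrix aligned to window-mean speed."""

    window_start_s: np.ndarray  # (n_windows,)
    features: np.ndarray  # (n_windows, n_features)
    feature_names: list[str]  # "<channel>_<band>"
    speed: np.ndarray  # (n_windows,) window-mean speed, units/s

    def __post_init__(self) -> None:
        n = len(self.window_start_s)
        if self.features.shape[0] != n or len(self.speed) != n:
            raise ValueError("row count mismatch between starts, features, speed")
        if self.features.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length does not match feature columns")

    @property
    def n_windows(self) -> int:
        return len(self.window_start_s)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df.insert(0, "window_start_s", self.window_start_s)
        df.insert(1, "speed", self.speed)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        names = [c for c in df.columns if c not in ("window_start_s", "speed")]
        return cls(
            window_start_s=df["window_start_s"].to_numpy(dtype=float),
            features=df[names].to_numpy(dtype=float),
            feature_names=list(names),
            speed=df["speed"].to_numpy(dtype=float),
        )

    def with_speed(self, speed: np.ndarray) -> "FeatureTable":
        return replace(self, speed=np.asarray(speed, dtype=float))


def detrend_linear(session: RecordingSession) -> RecordingSession:
    """Remove the per-channel least-squares linear trend."""
    if session.n_samples < 2:
        raise ValueError("need at least 2 samples per channel to detrend")
    data = signal.detrend(np.asarray(session.data, dtype=float), axis=1, type="linear")
    return RecordingSession(
        data=data,
        fs=session.fs,
        channel_names=list(session.channel_names),
        hippocampal_mask=np.asarray(session.hippocampal_mask).copy(),
        reference_note=session.reference_note,
    )


def band_power(session: RecordingSession, band: BandSpec) -> np.ndarray:
    """Continuous band-limited power (Hilbert envelope) per channel.

    A 4th-order Butterworth band-pass is applied forward and reverse
    (zero phase, effective order 8) with reflected edge padding, then the
    magnitude of the analytic signal is taken.  Output has the same
    channel x sample shape as the input.
    """
    band.validate_for(session.fs)
    sos = signal.butter(
        4, [band.lo, band.hi], btype="bandpass", fs=session.fs, output="sos"
    )
    x = np.asarray(session.data, dtype=float)
    filtered = signal.sosfiltfilt(sos, x, axis=1, padtype="even")
    n = filtered.shape[1]
    n_fft = int(fft.next_fast_len(n))
    analytic = signal.hilbert(filtered, N=n_fft, axis=1)[..., :n]
    return np.abs(analytic)


def _window_starts(total_s: float, wspec: WindowSpec) -> np.ndarray:
    # only complete windows [t, t + length) are kept
    n_win = int(np.floor((total_s - wspec.length_s) / wspec.hop_s + 1e-9)) + 1
    if n_win < 1:
        raise ValueError(
            f"signal of {total_s:.3f} s shorter than one {wspec.length_s:.3f}-s window"
        )
    return np.arange(n_win) * wspec.hop_s


def _window_means(values: np.ndarray, t: np.ndarray, starts: np.ndarray,
                  length_s: float) -> np.ndarray:
    """Mean of ``values`` (sampled at times ``t``) over [start, start+length)."""
    cs = np.concatenate([[0.0], np.cumsum(values, dtype=float)])
    i0 = np.searchsorted(t, starts - 1e-12, side="left")
    i1 = np.searchsorted(t, starts + length_s - 1e-12, side="left")
    counts = i1 - i0
    if np.any(counts < 1):
        raise ValueError("a window contains no samples")
    return (cs[i1] - cs[i0]) / counts


def window_features(
    power: dict[str, np.ndarray] | np.ndarray,
    trace: BehavioralTrace,
    session_fs: float,
    wspec: WindowSpec = WindowSpec(),
    channel_names: list[str] | None = None,
) -> FeatureTable:
    """Average power series and speed over half-overlapping windows.

    ``power`` maps band name -> channel x sample envelope matrix (or is a
    single such matrix, taken as one unnamed band).  Windows are the
    half-open intervals [t, t+length) for t = 0, hop, 2*hop, ...; only
    complete windows are kept, so a T-second session yields
    floor((T - length)/hop) + 1 rows.
    """
    if isinstance(power, np.ndarray):
        power = {"power": power}
    first = next(iter(power.values()))
    n_channels, n_samples = first.shape
    total_s = n_samples / session_fs
    if trace.duration_s + 1e-9 < total_s:
        raise ValueError("behavioural trace shorter than the power series")
    if channel_names is None:
        channel_names = [f"ch{c}" for c in range(n_channels)]

    starts = _window_starts(total_s, wspec)
    t_sig = np.arange(n_samples) / session_fs

    cols: list[np.ndarray] = []
    names: list[str] = []
    for band_name, mat in power.items():
        if mat.shape != (n_channels, n_samples):
            raise ValueError("all band matrices must share one channel x sample shape")
        for c in range(n_channels):
            cols.append(_window_means(mat[c], t_sig, starts, wspec.length_s))
            names.append(f"{channel_names[c]}_{band_name}")
    feats = np.column_stack(cols)
    speed = _window_means(trace.speed, trace.t, starts, wspec.length_s)
    return FeatureTable(
        window_start_s=starts, features=feats, feature_names=names, speed=speed
    )


def normalize_features(table: FeatureTable) -> FeatureTable:
    """Natural-log transform then z-score each feature column.

    The z-score uses the whole session (sample SD, n-1 denominator), so
    it precedes any cross-validation split.
    """
    logged = np.log(table.features + _LOG_EPS)
    mu = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"zero-variance feature column(s): {[table.feature_names[i] for i in bad]}"
        )
    z = (logged - mu) / sd
    return FeatureTable(
        window_start_s=table.window_start_s.copy(),
        features=z,
        feature_names=list(table.feature_names),
        speed=table.speed.copy(),
    )


def extract_features(
    session: RecordingSession,
    trace: BehavioralTrace,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    wspec: WindowSpec = WindowSpec(),
    normalize: bool = True,
) -> FeatureTable:
    """Full feature pipeline on the hippocampal channels of a session."""
    mask = np.asarray(session.hippocampal_mask, dtype=bool)
    if not mask.any():
        raise ValueError("session has no hippocampal channels")
    hippo = RecordingSession(
        data=np.asarray(session.data)[mask],
        fs=session.fs,
        channel_names=[n for n, m in zip(session.channel_names, mask) if m],
        hippocampal_mask=np.ones(int(mask.sum()), dtype=bool),
        reference_note=session.reference_note,
    )
    detrended = detrend_linear(hippo)
    power = {band.name: band_power(detrended, band) for band in bands}
    table = window_features(
        power, trace, session.fs, wspec, channel_names=hippo.channel_names
    )
    return normalize_features(table) if normalize else table
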