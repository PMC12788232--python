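"""sEMG envelope chain: band-pass, rectify, low-pass, normalize, time-normalize.

The chain turns one raw multi-channel trial into a muscles x 100 activation
profile, and averages the six trials of a session into the single
representative matrix D that enters the factorization.  All filters are
zero-phase (forward-backward Butterworth), so temporal features downstream
are not biased by phase lag; the nominal order is the design order before
the forward-backward doubling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .synthgen import Session, Trial

__all__ = [
    "PreprocessConfig",
    "MovementCycle",
    "ActivationMatrix",
    "bandpass_filter",
    "rectify",
    "envelope",
    "normalize",
    "time_normalize",
    "average_trials",
    "preprocess_trial",
    "process_session",
]


@dataclass(frozen=True)
class PreprocessConfig:
    bandpass_low: float = 20.0
    bandpass_high: float = 400.0
    bandpass_order: int = 4
    lowpass_cutoff: float = 20.0
    lowpass_order: int = 4
    n_points: int = 100
    normalization: str = "mvc"          # "mvc" or "task_max"
    sampling_rate: float = 2000.0

    def __post_init__(self) -> None:
        nyq = self.sampling_rate / 2.0
        if not 0 < self.bandpass_low < self.bandpass_high:
            raise ValueError("need 0 < bandpass_low < bandpass_high")
        if self.bandpass_high >= nyq:
            raise ValueError(
                f"bandpass_high={self.bandpass_high} must be below the "
                f"Nyquist frequency {nyq}")
        if self.lowpass_cutoff >= nyq:
            raise ValueError(
                f"lowpass_cutoff={self.lowpass_cutoff} must be below the "
                f"Nyquist frequency {nyq}")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.normalization not in ("mvc", "task_max"):
            raise ValueError("normalization must be 'mvc' or 'task_max'")


@dataclass(frozen=True)
class MovementCycle:
    """One side-kick cycle in sample indices, with the five phase marks a-e."""

    start_sample: int
    end_sample: int
    phase_marks: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        if self.start_sample >= self.end_sample:
            raise ValueError("cycle start must precede cycle end")
        marks = self.phase_marks
        if any(b < a for a, b in zip(marks, marks[1:])):
            raise ValueError("phase marks must be non-decreasing")
        if marks[0] < self.start_sample or marks[-1] > self.end_sample:
            raise ValueError("phase marks must lie within [start, end]")

    @classmethod
    def from_trial(cls, trial: Trial) -> "MovementCycle":
        marks = tuple(int(round(trial.events_s[k] * trial.sampling_rate))
                      for k in ("a", "b", "c", "d", "e"))
        return cls(start_sample=marks[0], end_sample=marks[-1],
                   phase_marks=marks)  # type: ignore[arg-type]


@dataclass(frozen=True)
class ActivationMatrix:
    """Averaged, normalized muscle activity: muscles x n_points, entries >= 0."""

    values: np.ndarray
    muscle_labels: tuple[str, ...]
    n_trials_averaged: int = 1

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if len(self.muscle_labels) != self.values.shape[0]:
            raise ValueError("one label per matrix row required")
        if len(set(self.muscle_labels)) != len(self.muscle_labels):
            raise ValueError("muscle labels must be unique")
        if (self.values < -1e-12).any():
            raise ValueError("activation matrix must be non-negative")


def _as_2d(x: np.ndarray) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        return arr[None, :], True
    return arr, False


def bandpass_filter(sig: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Zero-phase Butterworth band-pass, applied per channel."""
    arr, squeeze = _as_2d(sig)
    if arr.shape[1] <= 3 * max(config.bandpass_order, 1) * 2:
        raise ValueError("signal too short for the configured filter order")
    sos = signal.butter(config.bandpass_order,
                        (config.bandpass_low, config.bandpass_high),
                        btype="bandpass", fs=config.sampling_rate,
                        output="sos")
    out = signal.sosfiltfilt(sos, arr, axis=-1)
    return out[0] if squeeze else out


def rectify(sig: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    return np.abs(np.asarray(sig, dtype=float))


def envelope(sig: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Zero-phase low-pass smoothing of the rectified signal (linear envelope)."""
    arr, squeeze = _as_2d(sig)
    if arr.shape[1] <= 3 * max(config.lowpass_order, 1) * 2:
        raise ValueError("signal too short for the configured filter order")
    sos = signal.butter(config.lowpass_order, config.lowpass_cutoff,
                        btype="lowpass", fs=config.sampling_rate, output="sos")
    out = signal.sosfiltfilt(sos, arr, axis=-1)
    return out[0] if squeeze else out


def normalize(env: np.ndarray, reference: np.ndarray | None = None,
              mode: str = "mvc",
              muscle_labels: tuple[str, ...] | None = None) -> np.ndarray:
    """Express each channel as a fraction of its reference amplitude.

    ``mvc`` divides by the supplied per-muscle maximum-voluntary-contraction
    amplitude; ``task_max`` divides by the channel's own maximum over the
    signal, making the per-channel peak exactly one.
    """
    arr, squeeze = _as_2d(env)
    if mode == "mvc":
        if reference is None:
            raise ValueError("mvc normalization requires reference amplitudes")
        ref = np.asarray(reference, dtype=float).reshape(-1)
        if ref.shape[0] != arr.shape[0]:
            raise ValueError("one reference per channel required")
        bad = np.nonzero(ref <= 0)[0]
        if bad.size:
            names = ([muscle_labels[i] for i in bad] if muscle_labels
                     else bad.tolist())
            raise ValueError(f"non-positive MVC reference for muscle(s) {names}")
    elif mode == "task_max":
        ref = arr.max(axis=1)
        if (ref <= 0).any():
            bad = np.nonzero(ref <= 0)[0]
            names = ([muscle_labels[i] for i in bad] if muscle_labels
                     else bad.tolist())
            raise ValueError(
                f"task_max normalization undefined for all-zero channel(s) "
                f"{names}")
    else:
        raise ValueError("mode must be 'mvc' or 'task_max'")
    out = arr / ref[:, None]
    return out[0] if squeeze else out


def time_normalize(env: np.ndarray, cycle: MovementCycle,
                   n_points: int = 100) -> np.ndarray:
    """Linearly resample the cycle segment onto ``n_points`` equal steps.

    Interpolation is piecewise linear, which preserves non-negativity and the
    segment endpoints exactly.
    """
    arr, squeeze = _as_2d(env)
    if cycle.end_sample >= arr.shape[1]:
        raise ValueError("cycle extends beyond the signal")
    if cycle.end_sample - cycle.start_sample < 1:
        raise ValueError("degenerate cycle: start equals end")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    grid = np.linspace(cycle.start_sample, cycle.end_sample, n_points)
    samples = np.arange(cycle.start_sample, cycle.end_sample + 1)
    out = np.empty((arr.shape[0], n_points))
    for ch in range(arr.shape[0]):
        out[ch] = np.interp(grid, samples, arr[ch, samples[0]:samples[-1] + 1])
    return out[0] if squeeze else out


def average_trials(trials: list[np.ndarray],
                   muscle_labels: tuple[str, ...]) -> ActivationMatrix:
    """Elementwise mean of time-normalized trials -> representative profile."""
    if len(trials) < 1:
        raise ValueError("need at least one trial")
    shapes = {np.asarray(t).shape for t in trials}
    if len(shapes) != 1:
        raise ValueError(f"trial shapes differ: {sorted(shapes)}")
    stacked = np.stack([np.asarray(t, dtype=float) for t in trials])
    return ActivationMatrix(values=np.clip(stacked.mean(axis=0), 0.0, None),
                            muscle_labels=tuple(muscle_labels),
                            n_trials_averaged=len(trials))


def preprocess_trial(trial: Trial, config: PreprocessConfig,
                     mvc: dict[str, float] | None = None,
                     muscle_labels: tuple[str, ...] | None = None,
                     cycle: MovementCycle | None = None) -> np.ndarray:
    """Full single-trial chain: filter, rectify, smooth, normalize, resample."""
    cfg = config
    if cfg.sampling_rate != trial.sampling_rate:
        cfg = replace(cfg, sampling_rate=trial.sampling_rate)
    x = bandpass_filter(trial.emg, cfg)
    x = envelope(rectify(x), cfg)
    if cfg.normalization == "mvc":
        if mvc is None or muscle_labels is None:
            raise ValueError("mvc normalization requires the MVC table and "
                             "muscle labels")
        ref = np.array([mvc[m] for m in muscle_labels])
        x = normalize(x, ref, mode="mvc", muscle_labels=muscle_labels)
    else:
        x = normalize(x, mode="task_max", muscle_labels=muscle_labels)
    cyc = cycle if cycle is not None else MovementCycle.from_trial(trial)
    x = time_normalize(x, cyc, cfg.n_points)
    return np.clip(x, 0.0, None)   # filtering can undershoot slightly


def process_session(session: Session, config: PreprocessConfig,
                    muscle_labels: tuple[str, ...]) -> ActivationMatrix:
    """Average the session's preprocessed trials into the NMF input matrix."""
    profiles = [preprocess_trial(t, config, mvc=session.mvc,
                                 muscle_labels=muscle_labels)
                for t in session.trials]
    return average_trials(profiles, muscle_labels)
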