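"""Seeded synthetic study generator with known ground-truth synergy structure.

The generator emulates the crossover study design: 18 athletes, three
conditioning protocols (ESG/RBG/SQG), six maximal side-kick trials per
session recorded on 15 sEMG channels at 2000 Hz, and three vertical jumps at
each of three post-intervention time points.

Raw-like EMG is synthesized as an amplitude-modulated, band-limited Gaussian
carrier: the intended activation envelope ``E = W·C`` (muscles x time)
multiplies a zero-mean 20-400 Hz carrier whose mean rectified amplitude is
one, so that the standard envelope chain (band-pass, rectify, 20 Hz low-pass)
approximately recovers ``E``.  Protocol effects are multiplicative modifiers
on selected muscle weights; jump flight times are drawn by inverting the
flight-time law h = g*t^2/8 from configured normal jump heights.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .muscles import MUSCLES, PHASE_MARKS, PROTOCOLS, TIME_POINTS_MIN

__all__ = [
    "GroundTruth",
    "GeneratorConfig",
    "Trial",
    "Session",
    "Subject",
    "StudyDataset",
    "default_protocol_effects",
    "generate_ground_truth",
    "synthesize_trial",
    "synthesize_activation_matrix",
    "generate_jump_heights",
    "generate_study",
]

GRAVITY = 9.81  # m/s^2

#: Default jump-height distribution (cm): protocol -> {minutes: (mean, sd)}.
#: Means/SDs follow the reported group values of the study design emulated.
DEFAULT_JUMP_TABLE: dict[str, dict[int, tuple[float, float]]] = {
    "ESG": {6: (49.1, 2.8), 8: (48.9, 2.7), 10: (47.5, 2.9)},
    "RBG": {6: (47.0, 2.9), 8: (46.2, 3.0), 10: (45.7, 3.1)},
    "SQG": {6: (46.5, 3.2), 8: (47.8, 3.1), 10: (46.2, 3.3)},
}

#: Fractions of the trial at which the five cycle marks a-e are placed.
_EVENT_FRACTIONS: dict[str, float] = {
    "a": 0.05, "b": 0.25, "c": 0.45, "d": 0.70, "e": 0.95,
}


@dataclass(frozen=True)
class GroundTruth:
    """Generative synergy structure: non-negative weights and coefficients.

    ``weights`` is muscles x synergies with unit-norm columns; ``coefficients``
    is synergies x 100 (single Gaussian bumps with distinct centers on the
    normalized 0-100 timeline); ``protocol_effects`` maps each protocol label
    to a per-muscle multiplicative weight modifier.
    """

    weights: np.ndarray
    coefficients: np.ndarray
    protocol_effects: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        W, C = np.asarray(self.weights), np.asarray(self.coefficients)
        if W.ndim != 2 or C.ndim != 2 or W.shape[1] != C.shape[0]:
            raise ValueError("weights (muscles x k) and coefficients (k x 100) "
                             "must have matching synergy counts")
        if C.shape[1] != 100:
            raise ValueError("coefficients must have exactly 100 columns")
        if (W < 0).any() or (C < 0).any():
            raise ValueError("ground-truth factors must be non-negative")
        norms = np.linalg.norm(W, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("weight columns must have unit Euclidean norm")
        for label, mod in self.protocol_effects.items():
            if np.asarray(mod).shape != (W.shape[0],):
                raise ValueError(f"protocol effect for {label!r} must have one "
                                 "multiplier per muscle")

    @property
    def n_muscles(self) -> int:
        return self.weights.shape[0]

    @property
    def n_synergies(self) -> int:
        return self.weights.shape[1]

    def modified_weights(self, protocol: str) -> np.ndarray:
        """Weights with the protocol's per-muscle multipliers applied."""
        _check_protocol(protocol, self.protocol_effects)
        return self.weights * self.protocol_effects[protocol][:, None]

    def envelope(self, protocol: str) -> np.ndarray:
        """Noise-free muscles x 100 activation envelope under a protocol."""
        return self.modified_weights(protocol) @ self.coefficients


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-generation settings; defaults are the emulated study conditions."""

    n_subjects: int = 18
    n_muscles: int = 15
    n_synergies_true: int = 3
    n_trials: int = 6
    noise_sd: float = 0.05            # fraction of mean signal amplitude
    trial_jitter: float = 0.10        # +/- fraction of trial duration
    trial_duration_s: float = 1.5
    carrier_band: tuple[float, float] = (20.0, 400.0)
    sampling_rate: float = 2000.0
    effect_magnitude: float = 0.30    # protocol weight boost (+30 %)
    subject_weight_sd: float = 0.05   # between-subject weight variability
    jump_subject_rho: float = 0.5     # share of jump variance from subjects
    jump_means_sds: dict[str, dict[int, tuple[float, float]]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_JUMP_TABLE))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_synergies_true >= self.n_muscles:
            raise ValueError("need fewer synergies than muscles")
        if not 0 <= self.jump_subject_rho < 1:
            raise ValueError("jump_subject_rho must be in [0, 1)")
        for protocol, table in self.jump_means_sds.items():
            for minutes, (mean, sd) in table.items():
                if mean <= 0:
                    raise ValueError(
                        f"jump mean for {protocol} at {minutes} min must be "
                        f"positive, got {mean}")
                if sd < 0:
                    raise ValueError("jump SD must be >= 0")

    def without_protocol_effects(self) -> "GeneratorConfig":
        """Null variant: no weight boosts, identical jump distributions.

        Every protocol shares the grand mean/SD of the configured jump table,
        so no systematic protocol difference exists anywhere in the dataset.
        """
        cells = [ms for tab in self.jump_means_sds.values()
                 for ms in tab.values()]
        mean = float(np.mean([m for m, _ in cells]))
        sd = float(np.mean([s for _, s in cells]))
        flat = {p: {t: (mean, sd) for t in TIME_POINTS_MIN} for p in PROTOCOLS}
        return replace(self, effect_magnitude=0.0, jump_means_sds=flat)


@dataclass(frozen=True)
class Trial:
    """One raw-like side-kick recording: channels x samples plus cycle events."""

    emg: np.ndarray                 # channels x samples, arbitrary units
    events_s: dict[str, float]      # cycle marks a-e, seconds from trial start
    sampling_rate: float

    def __post_init__(self) -> None:
        stamps = [self.events_s[k] for k in PHASE_MARKS]
        if any(b <= a for a, b in zip(stamps, stamps[1:])):
            raise ValueError("cycle events a-e must be strictly increasing")
        if stamps[-1] > self.emg.shape[1] / self.sampling_rate:
            raise ValueError("cycle events exceed trial duration")


@dataclass(frozen=True)
class Session:
    """One protocol visit: six kick trials, MVC references, jump flight times."""

    protocol: str
    trials: tuple[Trial, ...]
    mvc: dict[str, float]                   # muscle -> reference amplitude
    flight_times_s: np.ndarray              # time points x jumps (3 x 3)
    time_points_min: tuple[int, ...] = TIME_POINTS_MIN

    def __post_init__(self) -> None:
        if (self.flight_times_s <= 0).any():
            raise ValueError("flight times must be positive")


@dataclass(frozen=True)
class Subject:
    subject_id: str
    sessions: dict[str, Session]            # protocol -> session


@dataclass(frozen=True)
class StudyDataset:
    subjects: tuple[Subject, ...]
    ground_truth: GroundTruth | None
    config: GeneratorConfig
    #: per-subject ground truth (weights perturbed between subjects)
    subject_truths: tuple[GroundTruth, ...] = ()


def _check_protocol(protocol: str, table) -> None:
    if protocol not in table:
        raise ValueError(
            f"unknown protocol {protocol!r}; allowed: {sorted(table)}")


def default_protocol_effects(n_muscles: int = 15,
                             magnitude: float = 0.30,
                             muscle_labels: tuple[str, ...] | None = None,
                             ) -> dict[str, np.ndarray]:
    """Per-muscle multiplicative weight modifiers for the three protocols.

    ESG (squat + electrical stimulation) boosts hip/knee extensors of both
    legs (GM, RF, RFR); RBG (band lateral steps) boosts the lateral chain
    (VL, GMed); SQG is the reference condition (all ones).  Directions mirror
    the between-protocol weight differences of the emulated study; magnitudes
    are configuration, not claims.
    """
    labels = muscle_labels if muscle_labels is not None else MUSCLES[:n_muscles]
    if len(labels) != n_muscles:
        raise ValueError("muscle_labels length must equal n_muscles")
    idx = {m: i for i, m in enumerate(labels)}

    def boost(muscles: tuple[str, ...]) -> np.ndarray:
        mod = np.ones(n_muscles)
        for m in muscles:
            if m in idx:
                mod[idx[m]] = 1.0 + magnitude
        return mod

    return {"ESG": boost(("GM", "RF", "RFR")),
            "RBG": boost(("VL", "GMed")),
            "SQG": np.ones(n_muscles)}


def generate_ground_truth(n_muscles: int, n_synergies: int, seed=1, *,
                          max_cosine: float = 0.8,
                          max_attempts: int = 2000,
                          effect_magnitude: float = 0.30) -> GroundTruth:
    """Draw a ground-truth synergy structure.

    Weight columns are sparse non-negative draws (squared-exponential
    entries), unit-normalized and rejection-sampled until every pairwise
    cosine similarity is below ``max_cosine`` so the synergies are genuinely
    distinct.  Coefficient rows are single Gaussian bumps with distinct
    centers on the 0-100 normalized timeline.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n_synergies >= n_muscles:
        raise ValueError("n_synergies must be smaller than n_muscles")
    rng = np.random.default_rng(seed)

    W = None
    for _ in range(max_attempts):
        cand = rng.exponential(1.0, size=(n_muscles, n_synergies)) ** 2
        cand /= np.linalg.norm(cand, axis=0, keepdims=True)
        gram = cand.T @ cand
        off = gram[~np.eye(n_synergies, dtype=bool)]
        if off.size == 0 or off.max() < max_cosine:
            W = cand
            break
    if W is None:
        raise RuntimeError(
            f"could not draw {n_synergies} weight columns with pairwise "
            f"cosine < {max_cosine} in {max_attempts} attempts")

    t = np.linspace(0.0, 100.0, 100)
    span = np.linspace(15.0, 85.0, n_synergies)
    centers = span + rng.uniform(-5.0, 5.0, size=n_synergies)
    widths = rng.uniform(6.0, 10.0, size=n_synergies)
    C = np.exp(-0.5 * ((t[None, :] - centers[:, None]) / widths[:, None]) ** 2)

    effects = default_protocol_effects(n_muscles, effect_magnitude)
    return GroundTruth(weights=W, coefficients=C, protocol_effects=effects)


def _band_limited_carrier(rng: np.random.Generator, shape: tuple[int, int],
                          band: tuple[float, float], fs: float) -> np.ndarray:
    """Zero-mean band-limited random-phase carrier, unit mean rectified value.

    Band-limited Gaussian noise is amplitude-stabilized by dividing out its
    Hilbert envelope, leaving a constant-amplitude oscillation with random
    phase and the same occupied band.  Its rectified value then fluctuates
    only at twice the carrier frequencies (above the envelope low-pass), so
    the downstream envelope chain recovers the modulator with negligible
    multiplicative noise.
    """
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    amp = np.abs(signal.hilbert(x, axis=-1))
    carrier = x / np.where(amp > 0, amp, 1.0)
    scale = np.mean(np.abs(carrier), axis=-1, keepdims=True)
    return carrier / np.where(scale > 0, scale, 1.0)


def synthesize_trial(truth: GroundTruth, protocol: str, noise_sd: float,
                     seed=0, *, sampling_rate: float = 2000.0,
                     duration_s: float = 1.5, jitter: float = 0.10,
                     carrier_band: tuple[float, float] = (20.0, 400.0),
                     ) -> Trial:
    """Synthesize one raw-like EMG trial under a protocol.

    The ground-truth envelope (muscles x 100) is placed over the movement
    cycle [a, e] of a jittered-duration trial, upsampled by linear
    interpolation, and multiplied by independent per-channel band-limited
    carriers.  Gaussian noise with SD ``noise_sd`` times the mean envelope
    amplitude is added.
    """
    _check_protocol(protocol, truth.protocol_effects)
    rng = np.random.default_rng(seed)

    dur = duration_s * (1.0 + rng.uniform(-jitter, jitter))
    n = int(round(dur * sampling_rate))
    events = {k: f * dur for k, f in _EVENT_FRACTIONS.items()}

    E100 = truth.envelope(protocol)
    ia = int(round(events["a"] * sampling_rate))
    ie = int(round(events["e"] * sampling_rate))
    grid = np.linspace(ia, ie, 100)
    env = np.zeros((truth.n_muscles, n))
    samples = np.arange(ia, ie + 1)
    for ch in range(truth.n_muscles):
        env[ch, ia:ie + 1] = np.interp(samples, grid, E100[ch])

    carrier = _band_limited_carrier(rng, env.shape, carrier_band, sampling_rate)
    raw = env * carrier
    if noise_sd > 0:
        raw = raw + noise_sd * E100.mean() * rng.standard_normal(raw.shape)
    return Trial(emg=raw, events_s=events, sampling_rate=sampling_rate)


def synthesize_activation_matrix(truth: GroundTruth, protocol: str = "SQG",
                                 noise_sd: float = 0.0, seed=0) -> np.ndarray:
    """Noisy activation matrix D = W·C + noise, clipped to be non-negative.

    Noise SD is ``noise_sd`` times the mean amplitude of the noise-free
    envelope; clipping at zero keeps D valid input for the factorization.
    """
    rng = np.random.default_rng(seed)
    D = truth.envelope(protocol)
    if noise_sd > 0:
        D = D + noise_sd * D.mean() * rng.standard_normal(D.shape)
    return np.clip(D, 0.0, None)


def generate_jump_heights(config: GeneratorConfig, rng: np.random.Generator,
                          ) -> dict[str, np.ndarray]:
    """Best-achievable jump heights (cm): protocol -> subjects x time points.

    Each subject carries a standard-normal factor shared across every
    protocol and time point; a cell's height is
    ``mean + sqrt(rho)*sd*z_subject + sqrt(1-rho)*sd*eps`` so the total
    between-subject variance equals the configured SD^2 while repeated
    measures correlate at about ``rho``.
    """
    z = rng.standard_normal(config.n_subjects)
    rho = config.jump_subject_rho
    out: dict[str, np.ndarray] = {}
    for protocol in PROTOCOLS:
        table = config.jump_means_sds[protocol]
        cols = []
        for minutes in TIME_POINTS_MIN:
            mean, sd = table[minutes]
            eps = rng.standard_normal(config.n_subjects)
            h = mean + np.sqrt(rho) * sd * z + np.sqrt(1 - rho) * sd * eps
            cols.append(np.clip(h, 1.0, None))
        out[protocol] = np.column_stack(cols)
    return out


def _height_cm_to_flight_time(h_cm: np.ndarray) -> np.ndarray:
    # invert h = g t^2 / 8 (h in metres)
    return np.sqrt(8.0 * (h_cm / 100.0) / GRAVITY)


def _perturb_subject_truth(truth: GroundTruth, sd: float,
                           rng: np.random.Generator) -> GroundTruth:
    """Per-subject ground truth: weights jittered multiplicatively, renormed."""
    if sd <= 0:
        return truth
    W = truth.weights * np.clip(1.0 + sd * rng.standard_normal(
        truth.weights.shape), 0.0, None)
    norms = np.linalg.norm(W, axis=0, keepdims=True)
    W = W / np.where(norms > 0, norms, 1.0)
    return GroundTruth(weights=W, coefficients=truth.coefficients,
                       protocol_effects=truth.protocol_effects)


def generate_study(config: GeneratorConfig | None = None) -> StudyDataset:
    """Generate the full seeded crossover dataset.

    One global seed fans out through ``numpy.random.SeedSequence`` to
    independent child streams per stage and per subject, so the dataset is
    reproducible byte for byte for a fixed configuration.
    """
    config = config or GeneratorConfig()
    root = np.random.SeedSequence(config.seed)
    ss_truth, ss_subjects, ss_jumps = root.spawn(3)

    truth = generate_ground_truth(
        config.n_muscles, config.n_synergies_true,
        np.random.default_rng(ss_truth),
        effect_magnitude=config.effect_magnitude)

    jump_rng = np.random.default_rng(ss_jumps)
    best_heights = generate_jump_heights(config, jump_rng)
    jump_gap_rng = np.random.default_rng(ss_jumps.spawn(1)[0])

    labels = MUSCLES[:config.n_muscles] if config.n_muscles <= len(MUSCLES) \
        else tuple(f"M{i:02d}" for i in range(config.n_muscles))

    subjects = []
    subject_truths = []
    for si, ss_subj in enumerate(root.spawn(config.n_subjects)):
        subj_rng = np.random.default_rng(ss_subj)
        s_truth = _perturb_subject_truth(truth, config.subject_weight_sd,
                                         subj_rng)
        subject_truths.append(s_truth)

        # MVC reference: above the subject's largest envelope in any protocol
        env_max = np.max([s_truth.envelope(p).max(axis=1) for p in PROTOCOLS],
                         axis=0)
        floor = 0.01 * max(env_max.max(), 1.0)
        mvc_vals = 1.1 * np.maximum(env_max, floor) \
            * (1.0 + 0.05 * subj_rng.random(config.n_muscles))

        sessions = {}
        for protocol in PROTOCOLS:
            trials = tuple(
                synthesize_trial(
                    s_truth, protocol, config.noise_sd,
                    seed=np.random.default_rng(child),
                    sampling_rate=config.sampling_rate,
                    duration_s=config.trial_duration_s,
                    jitter=config.trial_jitter,
                    carrier_band=config.carrier_band)
                for child in ss_subj.spawn(config.n_trials))
            best = best_heights[protocol][si]          # per time point, cm
            gaps = jump_gap_rng.exponential(1.0, size=(len(TIME_POINTS_MIN), 2))
            heights = np.column_stack([best, np.clip(best[:, None] - gaps,
                                                     0.5, None)])
            order = jump_gap_rng.permuted(
                np.broadcast_to(np.arange(3), heights.shape), axis=1)
            heights = np.take_along_axis(heights, order, axis=1)
            sessions[protocol] = Session(
                protocol=protocol, trials=trials,
                mvc=dict(zip(labels, mvc_vals)),
                flight_times_s=_height_cm_to_flight_time(heights))
        subjects.append(Subject(subject_id=f"S{si + 1:02d}", sessions=sessions))

    return StudyDataset(subjects=tuple(subjects), ground_truth=truth,
                        config=config, subject_truths=tuple(subject_truths))
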