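"""Seeded synthetic-data generators used throughout the test suite.

Two generators are provided.  ``generate_grouped_mixture`` draws grouped
Gaussian-mixture data with known shared components — the exact generative
assumption of the HDP mixture — for validating the collapsed Gibbs sampler
and the classifier.  ``generate_fhr`` builds FHR-like 4 Hz traces (smooth
baseline drift, AR(1)-style short-term variability, sparse accelerations and
decelerations) and then corrupts them with spike artifacts (> 25 bpm jumps)
and zeroed gaps of known positions and durations, so the preprocessing rules
can be validated in closed loop against the injected-defect ledger.  The
simulator aims at exercising the pipeline, not at physiological fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import SAMPLING_RATE, RawRecording


@dataclass
class MixtureSpec:
    """Grouped Gaussian mixture with shared components across groups."""

    means: np.ndarray            # (K_true × q)
    covariances: np.ndarray      # (K_true × q × q), SPD
    weights: np.ndarray          # (J × K_true), rows sum to 1
    m_per_group: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        K, q = self.means.shape
        if self.covariances.shape != (K, q, q):
            raise ValueError("covariances must be (K x q x q)")
        for c in self.covariances:
            if not np.allclose(c, c.T) or np.any(np.linalg.eigvalsh(c) <= 0):
                raise ValueError("covariances must be symmetric positive definite")
        if self.weights.shape[1] != K:
            raise ValueError("weights must have K columns")
        if not np.allclose(self.weights.sum(axis=1), 1.0):
            raise ValueError("weight rows must sum to 1")

    @property
    def K_true(self) -> int:
        return self.means.shape[0]

    @property
    def J(self) -> int:
        return self.weights.shape[0]


def separated_mixture_spec(
    K_true: int = 3, q: int = 2, J: int = 6, m_per_group: int = 100,
    separation: float = 10.0, seed: int = 0,
) -> MixtureSpec:
    """Equal-weight spec with unit-variance components whose means sit
    ``separation`` standard deviations apart along coordinate axes."""
    means = np.zeros((K_true, q))
    for k in range(K_true):
        means[k, k % q] = separation * (1 + k // q)
        if k % 2:
            means[k] = -means[k]
    covs = np.tile(np.eye(q), (K_true, 1, 1))
    weights = np.full((J, K_true), 1.0 / K_true)
    return MixtureSpec(means=means, covariances=covs, weights=weights,
                       m_per_group=m_per_group, seed=seed)


def generate_grouped_mixture(
    spec: MixtureSpec,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Draw the grouped dataset; returns (group -> data, group -> labels)."""
    rng = np.random.default_rng(spec.seed)
    chols = [np.linalg.cholesky(c) for c in spec.covariances]
    data: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    q = spec.means.shape[1]
    for j in range(spec.J):
        z = rng.choice(spec.K_true, size=spec.m_per_group, p=spec.weights[j])
        X = np.empty((spec.m_per_group, q))
        for i, k in enumerate(z):
            X[i] = spec.means[k] + chols[k] @ rng.standard_normal(q)
        data[f"g{j}"] = X
        labels[f"g{j}"] = z
    return data, labels


@dataclass
class FHRSimSpec:
    """Knobs of the FHR-like signal simulator.

    Defaults give a plausible term-fetus trace: 140 bpm baseline wandering
    by ±10 bpm over minutes, beat-scale variability of a few bpm, occasional
    15–20 bpm accelerations/decelerations, sparse spike artifacts of ≥ 40 bpm
    and missing-data gaps whose durations straddle the 15 s rule.
    """

    baseline_bpm: float = 140.0
    drift_amplitude_bpm: float = 10.0
    stv_scale_bpm: float = 2.5
    event_rate_per_min: float = 1.0
    event_magnitude_bpm: float = 15.0
    spike_rate_per_min: float = 0.5
    spike_magnitude_bpm: float = 40.0
    gap_rate_per_min: float = 0.5
    gap_durations_s: tuple[float, ...] = (4.0, 8.0, 25.0)
    duration_minutes: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 100.0 <= self.baseline_bpm <= 180.0:
            raise ValueError("baseline must lie in [100, 180] bpm")
        if self.duration_minutes <= 0:
            raise ValueError("duration must be positive")


@dataclass
class InjectionLedger:
    """Ground truth of the injected defects, in sample indices."""

    spike_indices: list[int] = field(default_factory=list)
    short_gaps: list[tuple[int, int]] = field(default_factory=list)  # < 15 s
    long_gaps: list[tuple[int, int]] = field(default_factory=list)   # >= 15 s


def generate_fhr(
    spec: FHRSimSpec,
) -> tuple[RawRecording, np.ndarray, InjectionLedger]:
    """Simulate one corrupted recording.

    Returns the corrupted recording, the uncorrupted truth signal and the
    ledger of injected spikes and gaps.  Defect sites are kept disjoint and
    away from the signal boundaries so each rule fires unambiguously.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_minutes * 60.0 * SAMPLING_RATE))

    # smooth baseline drift: two incommensurate slow sinusoids
    t = np.arange(n) / SAMPLING_RATE
    phase = rng.uniform(0, 2 * np.pi, size=2)
    drift = spec.drift_amplitude_bpm * (
        0.6 * np.sin(2 * np.pi * t / 300.0 + phase[0])
        + 0.4 * np.sin(2 * np.pi * t / 97.0 + phase[1]))

    # AR(1) short-term variability
    ar = np.empty(n)
    ar[0] = 0.0
    rho = 0.9
    innov = rng.standard_normal(n) * spec.stv_scale_bpm * np.sqrt(1 - rho ** 2)
    for i in range(1, n):
        ar[i] = rho * ar[i - 1] + innov[i]

    # sparse accelerations / decelerations as raised-cosine bumps
    events = np.zeros(n)
    n_events = rng.poisson(spec.event_rate_per_min * spec.duration_minutes)
    for _ in range(n_events):
        width = int(rng.uniform(15, 60) * SAMPLING_RATE)
        center = rng.integers(width, max(n - width, width + 1))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        mag = sign * spec.event_magnitude_bpm * rng.uniform(0.7, 1.3)
        lo, hi = center - width // 2, center + width // 2
        window = np.hanning(hi - lo)
        events[lo:hi] += mag * window

    truth = spec.baseline_bpm + drift + ar + events
    truth = np.clip(truth, 60.0, 220.0)

    corrupted = truth.copy()
    ledger = InjectionLedger()
    margin = int(20 * SAMPLING_RATE)
    occupied = np.zeros(n, dtype=bool)
    occupied[:margin] = occupied[-margin:] = True

    def _claim(start: int, end: int, pad: int) -> bool:
        lo, hi = max(start - pad, 0), min(end + pad, n)
        if occupied[lo:hi].any():
            return False
        occupied[lo:hi] = True
        return True

    n_spikes = rng.poisson(spec.spike_rate_per_min * spec.duration_minutes)
    for _ in range(n_spikes):
        i = int(rng.integers(margin, n - margin))
        if not _claim(i, i + 1, pad=int(5 * SAMPLING_RATE)):
            continue
        corrupted[i] = truth[i] + spec.spike_magnitude_bpm
        ledger.spike_indices.append(i)

    n_gaps = rng.poisson(spec.gap_rate_per_min * spec.duration_minutes)
    for _ in range(n_gaps):
        dur_s = float(rng.choice(spec.gap_durations_s))
        width = int(round(dur_s * SAMPLING_RATE))
        start = int(rng.integers(margin, n - margin - width))
        if not _claim(start, start + width, pad=int(5 * SAMPLING_RATE)):
            continue
        corrupted[start:start + width] = 0.0
        span = (start, start + width)
        if dur_s < 15.0:
            ledger.short_gaps.append(span)
        else:
            ledger.long_gaps.append(span)

    raw = RawRecording(samples=corrupted, record_id=f"sim{spec.seed}")
    return raw, truth, ledger


def two_class_feature_cohort(
    n_per_class: int = 8,
    m_segments: int = 12,
    n_features: int = 14,
    separation: float = 10.0,
    seed: int = 0,
):
    """Desk-scale two-class cohort of 14-feature recordings for end-to-end
    classifier checks: class means differ by ``separation`` noise SDs along
    the first two features; qualities are drawn in [0.6, 1].

    Returns a list of ``classify.RecordingFeatures``.
    """
    from .classify import HEALTHY, UNHEALTHY, RecordingFeatures

    rng = np.random.default_rng(seed)
    shift = np.zeros(n_features)
    shift[:2] = separation
    dataset = []
    for label, cls in ((HEALTHY, "h"), (UNHEALTHY, "u")):
        for r in range(n_per_class):
            base = rng.standard_normal(n_features)  # recording-level offset
            X = base + rng.standard_normal((m_segments, n_features))
            if label == UNHEALTHY:
                X = X + shift
            u = rng.uniform(0.6, 1.0, size=m_segments)
            dataset.append(RecordingFeatures(
                record_id=f"{cls}{r}", X=X, u=u, label=label))
    return dataset
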