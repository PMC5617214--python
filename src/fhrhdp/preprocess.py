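"""Cleaning and segmentation of raw 4 Hz fetal heart rate traces.

Raw cardiotocography FHR signals carry two kinds of defects: samples that
are plainly wrong (transducer slips producing jumps of more than 25 bpm
between successive samples) and samples that are missing outright (encoded
as 0 bpm).  Defective runs shorter than 15 s are refilled by shape-preserving
piecewise cubic Hermite (PCHIP) interpolation; longer runs are excised.
The cleaned signal is then cut into non-overlapping ``l``-second segments
taken from the last ``M`` minutes, each segment carrying a quality score
``u`` — the fraction of its samples that were actually measured rather than
interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

SAMPLING_RATE = 4.0  # Hz, fixed for this class of recordings

MEASURED = 0
INTERPOLATED = 1


@dataclass
class RawRecording:
    """A raw FHR trace in bpm at 4 Hz; 0 encodes a missing sample."""

    samples: np.ndarray
    record_id: str = ""
    ph: float | None = None
    sampling_rate: float = SAMPLING_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if np.any(self.samples < 0):
            raise ValueError("samples must be non-negative (0 = missing)")
        if self.sampling_rate != SAMPLING_RATE:
            raise ValueError("sampling_rate must be 4 Hz")


@dataclass
class CleanRecording:
    """Preprocessed FHR samples plus per-sample provenance.

    ``mask`` holds MEASURED/INTERPOLATED per retained sample;
    ``dropped_spans`` lists ``(start, end)`` half-open index ranges of the
    *original* signal that were excised.
    """

    samples: np.ndarray
    mask: np.ndarray
    dropped_spans: list[tuple[int, int]] = field(default_factory=list)
    record_id: str = ""
    ph: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.mask = np.asarray(self.mask, dtype=np.int8)
        if self.samples.shape != self.mask.shape:
            raise ValueError("mask must align with samples")


@dataclass
class Segment:
    """One ``l``-second block of clean signal with its quality score."""

    values: np.ndarray
    u: float
    index: int
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not 0.0 <= self.u <= 1.0:
            raise ValueError("quality u must lie in [0, 1]")


@dataclass
class CohortConfig:
    """Cohort labelling thresholds and the segmentation grid.

    ``tau0``/``tau1`` are umbilical-cord pH thresholds (healthy above tau0,
    unhealthy at or below tau1); ``minutes`` is the analysis window M and
    ``segment_seconds`` the segment length l.
    """

    tau0: float = 7.2
    tau1: float = 7.05
    minutes: float = 30.0
    segment_seconds: float = 10.0

    def __post_init__(self) -> None:
        if self.tau1 > self.tau0:
            raise ValueError("tau1 must not exceed tau0")
        if not 10.0 <= self.segment_seconds <= 30.0:
            raise ValueError("segment length must lie in [10, 30] seconds")
        if self.minutes <= 0:
            raise ValueError("analysis window must be positive")

    @property
    def n_segments(self) -> int:
        """m = M × 60 / l, the number of segments per recording."""
        m = self.minutes * 60.0 / self.segment_seconds
        if abs(m - round(m)) > 1e-9:
            raise ValueError("segment length must divide the analysis window")
        return int(round(m))


def detect_artifacts(raw: RawRecording, jump_threshold: float = 25.0) -> np.ndarray:
    """Flag missing (0 bpm) samples and >25 bpm successive-difference artifacts.

    The later sample of an offending pair is flagged, and the flagged run
    extends until the signal returns to within ``jump_threshold`` of the last
    accepted sample.
    """
    x = raw.samples
    if x.size == 0:
        raise ValueError("empty recording")
    flagged = np.zeros(x.size, dtype=bool)
    last_accepted: float | None = None
    for i, v in enumerate(x):
        if v == 0.0:
            flagged[i] = True
        elif last_accepted is None:
            last_accepted = v
        elif abs(v - last_accepted) > jump_threshold:
            flagged[i] = True
        else:
            last_accepted = v
    return flagged


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, end) spans of consecutive True entries."""
    spans = []
    in_run = False
    start = 0
    for i, f in enumerate(mask):
        if f and not in_run:
            in_run, start = True, i
        elif not f and in_run:
            in_run = False
            spans.append((start, i))
    if in_run:
        spans.append((start, len(mask)))
    return spans


def interpolate_gaps(
    raw: RawRecording, mask: np.ndarray, max_gap_s: float = 15.0
) -> CleanRecording:
    """Refill short flagged runs by PCHIP; excise runs of ``max_gap_s`` or more.

    Runs touching a signal boundary cannot be interpolated (no endpoint on one
    side) and are always excised.
    """
    x = raw.samples
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != x.shape:
        raise ValueError("mask must align with samples")
    good = ~mask
    if good.sum() < 2:
        raise ValueError("no valid data")

    max_gap_samples = int(round(max_gap_s * raw.sampling_rate))
    dropped: list[tuple[int, int]] = []
    interp_spans: list[tuple[int, int]] = []
    for start, end in _runs(mask):
        at_boundary = start == 0 or end == len(x)
        if at_boundary or (end - start) >= max_gap_samples:
            dropped.append((start, end))
        else:
            interp_spans.append((start, end))

    idx_good = np.flatnonzero(good)
    pchip = PchipInterpolator(idx_good, x[idx_good], extrapolate=False)

    filled = x.copy()
    provenance = np.full(x.size, MEASURED, dtype=np.int8)
    for start, end in interp_spans:
        filled[start:end] = pchip(np.arange(start, end))
        provenance[start:end] = INTERPOLATED

    keep = np.ones(x.size, dtype=bool)
    for start, end in dropped:
        keep[start:end] = False

    return CleanRecording(
        samples=filled[keep],
        mask=provenance[keep],
        dropped_spans=dropped,
        record_id=raw.record_id,
        ph=raw.ph,
    )


def clean_recording(raw: RawRecording, jump_threshold: float = 25.0,
                    max_gap_s: float = 15.0) -> CleanRecording:
    """Convenience: detect artifacts then interpolate/excise in one call."""
    return interpolate_gaps(raw, detect_artifacts(raw, jump_threshold), max_gap_s)


def segment_recording(clean: CleanRecording, cfg: CohortConfig) -> list[Segment]:
    """Cut the last M minutes of clean signal into m = M×60/l segments."""
    seg_len = int(round(cfg.segment_seconds * SAMPLING_RATE))
    total = int(round(cfg.minutes * 60.0 * SAMPLING_RATE))
    if clean.samples.size < total:
        raise ValueError("recording too short")
    m = cfg.n_segments
    tail = clean.samples[-total:]
    tail_mask = clean.mask[-total:]
    segments = []
    for i in range(m):
        sl = slice(i * seg_len, (i + 1) * seg_len)
        values = tail[sl]
        u = float(np.mean(tail_mask[sl] == MEASURED))
        segments.append(Segment(values=values, u=u, index=i,
                                recording_id=clean.record_id))
    return segments


HEALTHY = "healthy"
UNHEALTHY = "unhealthy"
EXCLUDED = "excluded"


def label_cohort(
    recordings: list[RawRecording],
    cfg: CohortConfig,
    balance: bool = False,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Label recordings healthy (pH > tau0) / unhealthy (pH <= tau1) / excluded.

    With ``balance=True`` the majority class is subsampled uniformly at random
    (seeded ``rng`` required) so both classes have equal counts; surplus
    recordings are marked excluded.
    """
    labels: dict[str, str] = {}
    for rec in recordings:
        if rec.ph is None:
            warnings.warn(f"recording {rec.record_id!r} has no pH; excluded")
            labels[rec.record_id] = EXCLUDED
        elif rec.ph > cfg.tau0:
            labels[rec.record_id] = HEALTHY
        elif rec.ph <= cfg.tau1:
            labels[rec.record_id] = UNHEALTHY
        else:
            labels[rec.record_id] = EXCLUDED
    if balance:
        if rng is None:
            raise ValueError("balancing requires a seeded rng")
        groups = {c: [r for r, lab in labels.items() if lab == c]
                  for c in (HEALTHY, UNHEALTHY)}
        n_min = min(len(groups[HEALTHY]), len(groups[UNHEALTHY]))
        for c, ids in groups.items():
            if len(ids) > n_min:
                keep = set(rng.choice(ids, size=n_min, replace=False))
                for r in ids:
                    if r not in keep:
                        labels[r] = EXCLUDED
    return labels
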