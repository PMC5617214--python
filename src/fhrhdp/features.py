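"""Per-segment FHR features: 9 time-domain and 5 frequency-domain.

The time-domain block holds the segment mean and standard deviation, the
short- and long-term variability (mean absolute successive difference;
mean per-minute range), the short- and long-term irregularity (interquartile
ranges of the successive-pair angle ``arctan(s(k+1)/s(k))`` and magnitude
``sqrt(s(k)^2 + s(k+1)^2)``), and the Poincaré-plot descriptors SD1, SD2 and
the complex correlation measure (CCM) of the beat-to-beat (RR) interval
series.  The frequency-domain block holds Welch band powers in four bands —
VLF 0–0.06 Hz, LF 0.06–0.3 Hz, MF 0.3–1 Hz, HF 1–2 Hz — plus the ratio
LF/(MF+HF).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .preprocess import SAMPLING_RATE, Segment

#: Canonical feature ordering used everywhere downstream.
FEATURE_NAMES = (
    "mean", "std", "v_stv", "v_ltv", "v_sti", "v_lti",
    "sd1", "sd2", "ccm",
    "p_vlf", "p_lf", "p_mf", "p_hf", "ratio",
)

BANDS = {
    "p_vlf": (0.0, 0.06),
    "p_lf": (0.06, 0.3),
    "p_mf": (0.3, 1.0),
    "p_hf": (1.0, 2.0),
}


@dataclass(frozen=True)
class FeatureVector:
    mean: float
    std: float
    v_stv: float
    v_ltv: float
    v_sti: float
    v_lti: float
    sd1: float
    sd2: float
    ccm: float
    p_vlf: float
    p_lf: float
    p_mf: float
    p_hf: float
    ratio: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def _iqr(x: np.ndarray) -> float:
    q1, q3 = np.percentile(x, [25.0, 75.0])
    return float(q3 - q1)


def time_domain_features(segment: Segment) -> tuple[float, ...]:
    """(mean, std, v_STV, v_LTV, v_STI, v_LTI) of one segment.

    Successive-pair statistics run over the K−1 valid pairs.  For segments of
    up to one minute the LTV "minute" is the whole segment with M its duration
    in fractional minutes; longer segments are split into whole-minute blocks.
    """
    s = np.asarray(segment.values, dtype=float)
    if s.size < 2:
        raise ValueError("segment must hold at least 2 samples")
    diffs = np.diff(s)
    v_stv = float(np.mean(np.abs(diffs)))

    minutes = s.size / (SAMPLING_RATE * 60.0)
    samples_per_min = int(SAMPLING_RATE * 60)
    if s.size <= samples_per_min:
        v_ltv = float((s.max() - s.min()) / minutes)
    else:
        n_blocks = s.size // samples_per_min
        ranges = [
            np.ptp(s[b * samples_per_min:(b + 1) * samples_per_min])
            for b in range(n_blocks)
        ]
        v_ltv = float(np.mean(ranges))

    with np.errstate(divide="ignore"):
        angles = np.arctan2(s[1:], s[:-1])
    v_sti = _iqr(angles)
    v_lti = _iqr(np.sqrt(s[:-1] ** 2 + s[1:] ** 2))
    return (float(np.mean(s)), float(np.std(s, ddof=1)), v_stv, v_ltv, v_sti, v_lti)


def fhr_to_rr(values: np.ndarray) -> np.ndarray:
    """Beat-to-beat intervals in seconds: RR = 60 / FHR."""
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        raise ValueError("FHR values must be positive")
    return 60.0 / v


def autocorrelation(rr: np.ndarray, lag: int) -> float:
    """Non-centered, bias-corrected autocorrelation γ(k) of the RR series."""
    rr = np.asarray(rr, dtype=float)
    n = rr.size
    k = abs(lag)
    if k >= n:
        raise ValueError("lag exceeds series length")
    return float(np.dot(rr[: n - k], rr[k:]) / (n - k))


def poincare_features(rr: np.ndarray) -> tuple[float, float, float]:
    """Poincaré descriptors (SD1, SD2) and CCM at lag m = 1.

    SD1² = γ(0) − γ(1) and SD2² = γ(0) + γ(1) − 2·RR̄² with the non-centered
    autocorrelation; CCM(1) = [γ(1) − 2γ(0) + 2γ(2) − γ(3)] / (2·Cn·(N−2)),
    Cn = π·SD1·SD2 (γ(−1) = γ(1) by symmetry).  Negative squared descriptors
    are clipped to zero; if Cn = 0 the CCM is returned as 0.
    """
    rr = np.asarray(rr, dtype=float)
    n = rr.size
    if n < 5:
        raise ValueError("RR series too short for CCM at m = 1")
    g0, g1, g2, g3 = (autocorrelation(rr, k) for k in range(4))
    rr_mean = float(np.mean(rr))

    sd1_sq = g0 - g1
    sd2_sq = g0 + g1 - 2.0 * rr_mean ** 2
    if sd1_sq < 0 or sd2_sq < 0:
        warnings.warn("negative squared Poincaré descriptor clipped to 0")
    sd1 = float(np.sqrt(max(sd1_sq, 0.0)))
    sd2 = float(np.sqrt(max(sd2_sq, 0.0)))

    c_n = np.pi * sd1 * sd2
    if c_n == 0.0:
        warnings.warn("degenerate Poincaré plot; CCM undefined, returning 0")
        return sd1, sd2, 0.0
    ccm = (g1 - 2.0 * g0 + 2.0 * g2 - g3) / (2.0 * c_n * (n - 2))
    return sd1, sd2, float(ccm)


def frequency_features(segment: Segment) -> tuple[float, float, float, float, float]:
    """Band powers (VLF, LF, MF, HF) and the LF/(MF+HF) ratio.

    Welch periodogram of the mean-removed segment (Hann window, one window
    spanning the whole segment); band power is the PSD integrated over each
    half-open band [lo, hi) so the four powers are additive.
    """
    s = np.asarray(segment.values, dtype=float)
    if s.size < 40:
        raise ValueError("segment must hold at least 40 samples")
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite values in segment")
    freqs, psd = welch(s - s.mean(), fs=SAMPLING_RATE, window="hann",
                       nperseg=s.size, detrend=False)
    df = freqs[1] - freqs[0]
    powers = []
    for name, (lo, hi) in BANDS.items():
        sel = (freqs >= lo) & ((freqs < hi) | (hi >= freqs[-1]))
        powers.append(float(np.sum(psd[sel]) * df))
    p_vlf, p_lf, p_mf, p_hf = powers
    denom = p_mf + p_hf
    if denom == 0.0:
        warnings.warn("zero MF+HF power; ratio undefined, returning 0")
        ratio = 0.0
    else:
        ratio = p_lf / denom
    return p_vlf, p_lf, p_mf, p_hf, ratio


def extract_feature_vector(segment: Segment) -> FeatureVector:
    """All 14 features of one segment, in canonical order."""
    try:
        mean, std, v_stv, v_ltv, v_sti, v_lti = time_domain_features(segment)
        rr = fhr_to_rr(segment.values)
        sd1, sd2, ccm = poincare_features(rr)
        p_vlf, p_lf, p_mf, p_hf, ratio = frequency_features(segment)
    except ValueError as exc:
        raise ValueError(
            f"segment {segment.index} of {segment.recording_id!r}: {exc}"
        ) from exc
    return FeatureVector(mean, std, v_stv, v_ltv, v_sti, v_lti,
                         sd1, sd2, ccm, p_vlf, p_lf, p_mf, p_hf, ratio)


def feature_matrix(segments: list[Segment]) -> tuple[np.ndarray, np.ndarray]:
    """Stack segment feature vectors into (m × 14) plus the quality vector u."""
    X = np.vstack([extract_feature_vector(seg).as_array() for seg in segments])
    u = np.array([seg.u for seg in segments])
    return X, u
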