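"""Evoked field-potential plasticity analysis.

A recording is a 10-min pre-conditioning baseline and a 60-min
post-conditioning series of evoked FP peak amplitudes sampled at 0.1 Hz.
The pipeline: baseline-stability QC (discard if the linear fit of the
baseline has r^2 > 0.2), normalization to baseline mean, 1-min binning
(6 sweeps per point), the post/pre ratio (last 5 min post / last 5 min
pre), and a classification into LTD / no-change / LTP (>10% change plus
Welch-test significance).  Input-output curves yield the half-max
working point by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

#: Baseline-stability rejection threshold on r^2 of the linear fit.
BASELINE_R2_THRESHOLD = 0.2
#: Samples in a 5-min window at 0.1 Hz.
WINDOW_SAMPLES = 30


class Outcome(str, Enum):
    LTD = "LTD"
    NO_CHANGE = "no_change"
    LTP = "LTP"


@dataclass
class FPRecording:
    """Pre/post evoked FP peak-amplitude series at nominally 0.1 Hz."""

    pre_t: np.ndarray
    pre_amplitudes: np.ndarray
    post_t: np.ndarray
    post_amplitudes: np.ndarray
    sampling_hz: float = 0.1
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pre_t = np.asarray(self.pre_t, dtype=float)
        self.pre_amplitudes = np.asarray(self.pre_amplitudes, dtype=float)
        self.post_t = np.asarray(self.post_t, dtype=float)
        self.post_amplitudes = np.asarray(self.post_amplitudes, dtype=float)
        if self.pre_t.shape != self.pre_amplitudes.shape or self.post_t.shape != self.post_amplitudes.shape:
            raise ValueError("time and amplitude arrays must align")
        if not (np.all(np.isfinite(self.pre_amplitudes)) and np.all(np.isfinite(self.post_amplitudes))):
            raise ValueError("amplitudes must be finite")
        for t in (self.pre_t, self.post_t):
            if len(t) >= 2:
                dt = np.diff(t)
                if np.any(np.abs(dt - 1.0 / self.sampling_hz) > 0.5):
                    raise ValueError("sampling interval inconsistent with sampling_hz")


@dataclass(frozen=True)
class PlasticityOutcome:
    post_pre_ratio: float
    classification: Outcome
    baseline_r2: float
    test_p: float
    insufficient_samples: bool = False


def baseline_stability(pre_amplitudes, pre_t=None) -> float:
    """r^2 of the OLS fit of baseline amplitude against time.

    A perfectly flat baseline has undefined regression r^2; it is defined
    here as 0 (maximally stable).  Recordings with r^2 > 0.2 are
    conventionally discarded.
    """
    y = np.asarray(pre_amplitudes, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 baseline samples")
    x = np.asarray(pre_t, dtype=float) if pre_t is not None else np.arange(y.size, dtype=float)
    if np.ptp(y) == 0:
        return 0.0
    res = stats.linregress(x, y)
    return float(res.rvalue**2)


def is_stable(rec: FPRecording) -> bool:
    return baseline_stability(rec.pre_amplitudes, rec.pre_t) <= BASELINE_R2_THRESHOLD


def bin_1min(series, sampling_hz: float = 0.1) -> np.ndarray:
    """Average consecutive non-overlapping 1-min groups (6 samples at 0.1 Hz).

    A trailing partial bin is dropped, so every binned point represents
    exactly one minute of sweeps.
    """
    per_bin = int(round(60.0 * sampling_hz))
    y = np.asarray(series, dtype=float)
    n_bins = y.size // per_bin
    if n_bins == 0:
        return np.empty(0)
    return y[: n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1)


def normalize_to_baseline(rec: FPRecording) -> tuple[np.ndarray, np.ndarray]:
    """1-min binned (pre, post) series divided by the baseline mean."""
    base = rec.pre_amplitudes.mean()
    if base == 0:
        raise ValueError("baseline mean is zero")
    return bin_1min(rec.pre_amplitudes, rec.sampling_hz) / base, bin_1min(
        rec.post_amplitudes, rec.sampling_hz
    ) / base


def _window_mean(w: np.ndarray) -> float:
    # the mean of a constant window is that constant, exactly (keeps
    # noise-free synthetic ratios free of summation rounding)
    return float(w[0]) if np.ptp(w) == 0 else float(w.mean())


def post_pre_ratio(rec: FPRecording) -> float:
    """Mean of the last 5 min post / mean of the last 5 min pre."""
    if rec.pre_amplitudes.size < WINDOW_SAMPLES or rec.post_amplitudes.size < WINDOW_SAMPLES:
        raise ValueError("pre and post series must each cover at least 5 min")
    pre_mean = _window_mean(rec.pre_amplitudes[-WINDOW_SAMPLES:])
    if pre_mean == 0:
        raise ValueError("pre-conditioning window mean is zero")
    return _window_mean(rec.post_amplitudes[-WINDOW_SAMPLES:]) / pre_mean


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    # zero-variance windows (noise-free synthetic traces) have a degenerate
    # Welch statistic: define p = 0 for different means, 1 for equal means
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 0.0 if a.mean() != b.mean() else 1.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def classify_outcome(rec: FPRecording, alpha: float = 0.05) -> PlasticityOutcome:
    """LTD / no-change / LTP from the post/pre ratio plus a Welch test.

    LTD: ratio < 0.9 and p < alpha; LTP: ratio > 1.1 and p < alpha;
    anything else (including changes inside +/-10% or non-significant
    ones) is no-change.  The test compares the raw sweeps of the two
    5-min windows.
    """
    r2 = baseline_stability(rec.pre_amplitudes, rec.pre_t)
    try:
        ratio = post_pre_ratio(rec)
    except ValueError:
        return PlasticityOutcome(np.nan, Outcome.NO_CHANGE, r2, np.nan, insufficient_samples=True)
    p = _welch_p(rec.pre_amplitudes[-WINDOW_SAMPLES:], rec.post_amplitudes[-WINDOW_SAMPLES:])
    if ratio < 0.9 and p < alpha:
        cls = Outcome.LTD
    elif ratio > 1.1 and p < alpha:
        cls = Outcome.LTP
    else:
        cls = Outcome.NO_CHANGE
    return PlasticityOutcome(ratio, cls, r2, p)


@dataclass(frozen=True)
class IOCurve:
    """Input-output relation: evoked amplitude vs stimulus intensity (uA)."""

    stimulus_intensities: np.ndarray
    fp_amplitudes: np.ndarray
    fiber_volley_amplitudes: np.ndarray | None = None

    def __post_init__(self):
        i = np.asarray(self.stimulus_intensities, dtype=float)
        a = np.asarray(self.fp_amplitudes, dtype=float)
        if i.size != a.size or i.size < 2:
            raise ValueError("need >= 2 matched intensity/amplitude points")
        if np.any(np.diff(i) <= 0):
            raise ValueError("intensities must be strictly increasing")
        object.__setattr__(self, "stimulus_intensities", i)
        object.__setattr__(self, "fp_amplitudes", a)


def io_halfmax(curve: IOCurve) -> tuple[float, float]:
    """Half-max amplitude and the interpolated stimulus producing it.

    The half-max is max(FP)/2; the stimulus is found by linear
    interpolation between the bracketing intensities.  If the half-max
    lies below the first measured amplitude, extrapolation is refused.
    """
    amps = curve.fp_amplitudes
    stims = curve.stimulus_intensities
    half = float(amps.max()) / 2.0
    if half < amps[0]:
        raise ValueError("half-max below the first measured amplitude; refusing to extrapolate")
    idx = int(np.argmax(amps >= half))
    if amps[idx] == half:
        return half, float(stims[idx])
    lo, hi = idx - 1, idx
    frac = (half - amps[lo]) / (amps[hi] - amps[lo])
    return half, float(stims[lo] + frac * (stims[hi] - stims[lo]))
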