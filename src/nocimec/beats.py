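"""Beat segmentation and per-heartbeat vascular impedance estimation.

The arterial wall is modelled as a spring (stiffness K) and a damper
(viscosity B) in parallel across the vessel diameter.  Within one
heartbeat the change in arterial pressure drives the change in the
photoplethysmogram (PPG) wave height::

    dPb(t) = K * dPl(t) + B * dPl'(t)

where dPb, dPl and dPl' are the pressure, PPG and PPG-derivative series
re-zeroed at the beat onset t0 (the R wave).  One (K, B) pair is
estimated per heartbeat by ordinary least squares with no intercept;
beats with a coefficient of determination below 0.95 or a negative
coefficient are discarded from analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

logger = logging.getLogger("nocimec")

#: minimum coefficient of determination for a beat to enter the analysis
R2_THRESHOLD = 0.95
#: minimum number of samples for an identifiable two-parameter fit
MIN_BEAT_SAMPLES = 4

FEATURE_COLUMNS = ["beat_time", "K", "B", "r_squared", "valid", "hr", "sbp", "ppg_amp"]


class UnusableRecordError(ValueError):
    """The waveform record cannot support beat-wise analysis."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class WaveformRecord:
    """Synchronised multi-channel sampled record (ECG, ABP, PPG).

    Parameters
    ----------
    sampling_rate : float
        Samples per second, shared by all channels.
    ecg, abp, ppg : ndarray
        Sampled ECG voltage (a.u.), invasive arterial pressure (mmHg)
        and photoplethysmogram (a.u.).  Equal length.
    time_origin : float
        Time of the first sample, seconds.
    r_times : ndarray or None
        Optional R-wave annotations (seconds), strictly increasing and
        within the record span.
    """

    sampling_rate: float
    ecg: np.ndarray
    abp: np.ndarray
    ppg: np.ndarray
    time_origin: float = 0.0
    r_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.abp = np.asarray(self.abp, dtype=float)
        self.ppg = np.asarray(self.ppg, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not (len(self.ecg) == len(self.abp) == len(self.ppg)):
            raise ValueError("ecg, abp and ppg must have equal length")
        if self.r_times is not None:
            self.r_times = np.asarray(self.r_times, dtype=float)
            if np.any(np.diff(self.r_times) <= 0):
                raise ValueError("r_times must be strictly increasing")
            if len(self.r_times) and (
                self.r_times[0] < self.time_origin - 0.5 / self.sampling_rate
                or self.r_times[-1] > self.time_origin + self.duration
            ):
                raise ValueError("r_times outside record span")

    @property
    def n_samples(self) -> int:
        return len(self.abp)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return self.time_origin + np.arange(self.n_samples) / self.sampling_rate


@dataclass
class BeatSegment:
    """Difference series of one heartbeat, re-zeroed at the beat onset.

    ``dpb``, ``dpl`` and ``dpl_dot`` are all zero at the first sample by
    construction.  ``index_range`` locates the beat in the parent record
    (half-open sample slice) when the segment was cut from one.
    """

    t0: float
    dpb: np.ndarray
    dpl: np.ndarray
    dpl_dot: np.ndarray
    r_interval: float
    index_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.dpb = np.asarray(self.dpb, dtype=float)
        self.dpl = np.asarray(self.dpl, dtype=float)
        self.dpl_dot = np.asarray(self.dpl_dot, dtype=float)
        if not (len(self.dpb) == len(self.dpl) == len(self.dpl_dot)):
            raise ValueError("difference series must have equal length")
        if len(self.dpb) < MIN_BEAT_SAMPLES:
            raise ValueError(f"beat needs >= {MIN_BEAT_SAMPLES} samples")

    @property
    def n_samples(self) -> int:
        return len(self.dpb)


@dataclass
class BeatEstimate:
    """Per-beat impedance estimate with its quality-control verdict."""

    K: float
    B: float
    r_squared: float
    valid: bool
    reason: str | None = None


# ---------------------------------------------------------------------------
# R-wave detection and segmentation
# ---------------------------------------------------------------------------

def detect_r_waves(record: WaveformRecord) -> np.ndarray:
    """Return R-wave times (seconds) for `record`.

    Annotations take precedence: if ``record.r_times`` is present it is
    returned verbatim.  Otherwise peaks are detected on the ECG channel
    (amplitude above half the maximum excursion, at least 200 ms apart),
    which matches the impulse-marker ECG emitted by the simulator as
    well as any reasonably clean QRS-dominated trace.
    """
    if record.r_times is not None:
        if len(record.r_times) < 2:
            raise UnusableRecordError("fewer than 2 annotated R waves")
        return np.asarray(record.r_times, dtype=float)
    if record.duration < 2.0:
        raise UnusableRecordError("record shorter than 2 s")
    ecg = record.ecg
    if np.ptp(ecg) == 0:
        raise UnusableRecordError("flat ECG channel, no beats detectable")
    height = ecg.min() + 0.5 * np.ptp(ecg)
    distance = max(1, int(round(0.2 * record.sampling_rate)))
    peaks, _ = find_peaks(ecg, height=height, distance=distance)
    # plateau-free impulse trains: first/last sample can be a peak too
    if len(ecg) > 1 and ecg[0] >= height and ecg[0] > ecg[1]:
        peaks = np.concatenate([[0], peaks])
    if len(peaks) < 2:
        raise UnusableRecordError("fewer than 2 beats detected on ECG")
    return record.time_origin + peaks / record.sampling_rate


def segment_beats(record: WaveformRecord, r_times: np.ndarray) -> list[BeatSegment]:
    """Cut the ABP/PPG channels into per-beat difference series.

    One segment per RR interval, half-open ``[R_i, R_{i+1})``; the
    sample at ``R_{i+1}`` opens the next beat.  The PPG derivative is
    computed by second-order central differences within the beat window
    (one-sided at the window edges), then all three series are re-zeroed
    at the first sample.  Intervals shorter than four samples are
    skipped with a warning.
    """
    r_times = np.asarray(r_times, dtype=float)
    if len(r_times) < 2:
        raise UnusableRecordError("need at least 2 R-wave times")
    fs = record.sampling_rate
    idx = np.round((r_times - record.time_origin) * fs).astype(int)
    idx = np.clip(idx, 0, record.n_samples)
    segments: list[BeatSegment] = []
    dt = 1.0 / fs
    for i in range(len(idx) - 1):
        i0, i1 = idx[i], idx[i + 1]
        if i1 - i0 < MIN_BEAT_SAMPLES:
            logger.warning(
                "skipping beat at t=%.3f s: RR interval of %d samples (< %d)",
                r_times[i], i1 - i0, MIN_BEAT_SAMPLES,
            )
            continue
        pb = record.abp[i0:i1]
        pl = record.ppg[i0:i1]
        pl_dot = np.gradient(pl, dt)
        segments.append(
            BeatSegment(
                t0=r_times[i],
                dpb=pb - pb[0],
                dpl=pl - pl[0],
                dpl_dot=pl_dot - pl_dot[0],
                r_interval=r_times[i + 1] - r_times[i],
                index_range=(i0, i1),
            )
        )
    return segments


# ---------------------------------------------------------------------------
# impedance fit and quality control
# ---------------------------------------------------------------------------

def fit_beat_impedance(segment: BeatSegment) -> BeatEstimate:
    """Least-squares (K, B) for one beat, through the origin.

    Minimises ``sum((dPb - K*dPl - B*dPl')**2)`` over all samples of the
    beat.  The coefficient of determination is computed against the
    origin-constrained model (``SST = sum(dPb**2)``), so it can be
    negative.  A rank-deficient design (both regressors ~zero, or
    collinear) yields an invalid estimate with a reason code rather than
    an exception.
    """
    X = np.column_stack([segment.dpl, segment.dpl_dot])
    y = segment.dpb
    scale = np.abs(X).max()
    if scale == 0 or np.linalg.matrix_rank(X, tol=1e-12 * scale) < 2:
        return BeatEstimate(np.nan, np.nan, -np.inf, False, reason="degenerate design")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    K, B = float(coef[0]), float(coef[1])
    sse = float(np.sum((y - X @ coef) ** 2))
    sst = float(np.sum(y**2))
    if sst == 0.0:
        return BeatEstimate(K, B, -np.inf, False, reason="zero pressure variation")
    r2 = 1.0 - sse / sst
    valid = bool(K > 0 and B > 0 and r2 >= R2_THRESHOLD)
    reason = None
    if not valid:
        reason = "low r_squared" if r2 < R2_THRESHOLD else "negative coefficient"
    return BeatEstimate(K, B, r2, valid, reason=reason)


def passes_qc(estimate: BeatEstimate) -> bool:
    """Retention rule: r² >= 0.95 and K > 0 and B > 0."""
    return bool(
        np.isfinite(estimate.K)
        and np.isfinite(estimate.B)
        and estimate.r_squared >= R2_THRESHOLD
        and estimate.K > 0
        and estimate.B > 0
    )


def qc_filter(estimates: list[BeatEstimate]) -> list[BeatEstimate]:
    """Drop beats failing the retention rule; order preserved."""
    kept = [e for e in estimates if passes_qc(e)]
    removed = len(estimates) - len(kept)
    if removed:
        logger.info("quality control removed %d of %d beats", removed, len(estimates))
    return kept


# ---------------------------------------------------------------------------
# per-beat features
# ---------------------------------------------------------------------------

def extract_beat_features(
    record: WaveformRecord,
    segments: list[BeatSegment],
    estimates: list[BeatEstimate],
) -> pd.DataFrame:
    """Per-beat feature trace: K, HR, systolic BP and PPG amplitude.

    ``hr = 60 / RR``; ``sbp`` is the ABP maximum and ``ppg_amp`` the PPG
    peak-to-peak excursion within the beat window.  K is reported only
    for beats that survive quality control (NaN otherwise); B and r² are
    carried along for inspection.
    """
    if len(segments) != len(estimates):
        raise ValueError("segments and estimates must align one-to-one")
    rows = []
    for seg, est in zip(segments, estimates):
        if seg.index_range is None:
            raise ValueError("segment lacks a window into the record")
        i0, i1 = seg.index_range
        abp = record.abp[i0:i1]
        ppg = record.ppg[i0:i1]
        ok = passes_qc(est)
        rows.append(
            {
                "beat_time": seg.t0,
                "K": est.K if ok else np.nan,
                "B": est.B,
                "r_squared": est.r_squared,
                "valid": ok,
                "hr": 60.0 / seg.r_interval,
                "sbp": float(abp.max()),
                "ppg_amp": float(np.ptp(ppg)),
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def process_record(record: WaveformRecord) -> pd.DataFrame:
    """Full beat pipeline: R waves -> segments -> fits -> feature trace."""
    r_times = detect_r_waves(record)
    segments = segment_beats(record, r_times)
    estimates = [fit_beat_impedance(s) for s in segments]
    return extract_beat_features(record, segments, estimates)
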