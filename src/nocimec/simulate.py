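"""Synthetic hemodynamic records, stimulation sessions and cohorts.

Every generator is the exact inverse of one analysis stage, so the
pipeline can be tested against known ground truth:

* per-beat ABP is a smooth pulse template (raised-cosine systolic
  upstroke, exponential diastolic decay) on a diastolic baseline;
* the PPG channel is obtained by integrating the arterial-wall model
  ``dPl' = (dPb − K·dPl)/B`` within each beat, so the record satisfies
  the impedance relation at the scheduled (K, B) up to integration
  error;
* tetanus rungs at or above the subject's sympathetic threshold evoke
  a transient rise of K and systolic BP (and, through the model, a fall
  of PPG amplitude) peaking ~10 s post-stimulus; sub-threshold rungs
  perturb by well under the 5% detection threshold;
* a skin-incision segment realises a programmed systolic-BP ratio
  between incision and electrocautery;
* cohorts draw (MEC_K, ROC_BP) pairs from a linear model with Gaussian
  noise plus an out-of-range subgroup.

All generators are pure functions of their arguments and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .beats import WaveformRecord
from .response import IncisionWindow, OUT_OF_RANGE

DEFAULT_FS = 250.0          # samples/s, typical patient-monitor rate
_OVERSAMPLE = 8             # fine-grid factor for the wall-model integration

#: systolic upstroke duration of the pulse template, s
RISE_S = 0.12
#: diastolic decay time constant of the pulse template, s
DECAY_S = 0.25

#: evoked response peaks this long after the stimulus, s (observed 9.8-10.0 s)
RESPONSE_PEAK_S = 10.0
#: evoked response has returned to baseline this long after the stimulus, s
RESPONSE_END_S = 30.0


@dataclass
class SubjectGroundTruth:
    """True parameters of one simulated subject.

    ``sympathetic_threshold`` is the true MEC in mA (None = above the
    80 mA range).  ``response_gain`` (% per mA) sets the evoked change
    at rung c to ``gain·(c − threshold + step)`` percent, so the change
    at the threshold rung itself already exceeds 5%; sub-threshold
    rungs fluctuate by ``subthreshold_pct`` (< 5%).  ``ppg_gain``
    rescales the PPG channel (arbitrary units); fitted K and B scale
    inversely with it.
    """

    baseline_K: float = 1.5          # mmHg per PPG a.u.
    baseline_B: float = 0.2          # mmHg·s per PPG a.u.
    hr: float = 70.0                 # beats/min
    sbp_baseline: float = 100.0      # mmHg
    pulse_pressure: float = 40.0     # mmHg, held constant through responses
    ppg_gain: float = 1.0            # a.u. scale of the PPG channel
    ppg_dc: float = 10.0             # a.u. offset of the PPG channel
    sympathetic_threshold: float | None = 40.0   # mA; None = above range
    response_gain: float = 1.2       # % per mA above (threshold − step)
    subthreshold_pct: float = 2.0    # sub-threshold perturbation, %
    rocbp_true: float = 18.3         # programmed ROC_BP, %
    noise_sd: float = 0.0            # channel noise, fraction of pulse scale

    def __post_init__(self) -> None:
        if self.baseline_K <= 0 or self.baseline_B <= 0:
            raise ValueError("baseline_K and baseline_B must be positive")
        if self.subthreshold_pct >= 5.0:
            raise ValueError("sub-threshold perturbation must stay below 5%")


@dataclass
class CohortSpec:
    """Linear MEC_K → ROC_BP cohort structure with an out-of-range subgroup."""

    n_subjects: int = 30
    slope_true: float = -0.28        # % per mA
    intercept_true: float = 31.26    # %
    noise_sd: float = 5.0            # % on ROC_BP
    oor_fraction: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        if not 0 <= self.oor_fraction < 1:
            raise ValueError("oor_fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# waveform rendering
# ---------------------------------------------------------------------------

def _pulse_shape(tau: np.ndarray) -> np.ndarray:
    """Normalised pulse: raised-cosine upstroke then exponential decay."""
    out = np.empty_like(tau)
    rising = tau < RISE_S
    out[rising] = 0.5 * (1.0 - np.cos(np.pi * tau[rising] / RISE_S))
    out[~rising] = np.exp(-(tau[~rising] - RISE_S) / DECAY_S)
    return out


def _integrate_wall_model(dpb: np.ndarray, tau: np.ndarray,
                          K: float, B: float) -> np.ndarray:
    """Exact-kernel solution of dPl' = (dPb − K·dPl)/B with dPl(0) = 0."""
    if B <= 0:
        if K <= 0:
            raise ValueError("K and B cannot both be non-positive")
        return dpb / K  # quasi-static branch: damper removed
    kernel = np.exp(K * (tau - tau[-1]) / B)
    integral = cumulative_trapezoid(kernel * dpb, tau, initial=0.0)
    return integral / (B * kernel)


def _render(
    fs: float,
    r_idx: np.ndarray,
    n_samples: int,
    K_b: np.ndarray,
    B_b: np.ndarray,
    sys_b: np.ndarray,
    dia_b: np.ndarray,
    ppg_gain: float,
    ppg_dc: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render ECG/ABP/PPG channels from a per-beat parameter schedule.

    ``r_idx`` holds the beat-opening sample indices; the stretch after
    the last R is rendered as one more beat and truncated.
    """
    abp = np.empty(n_samples)
    ppg = np.empty(n_samples)
    ecg = np.zeros(n_samples)
    bounds = np.append(r_idx, n_samples)
    fine_dt = 1.0 / (fs * _OVERSAMPLE)
    for b in range(len(r_idx)):
        i0, i1 = bounds[b], bounds[b + 1]
        if i1 <= i0:
            continue
        n_fine = (i1 - i0) * _OVERSAMPLE
        tau = np.arange(n_fine) * fine_dt
        dpb = (sys_b[b] - dia_b[b]) * _pulse_shape(tau)
        dpl = _integrate_wall_model(dpb, tau, K_b[b], B_b[b])
        abp[i0:i1] = dia_b[b] + dpb[::_OVERSAMPLE]
        ppg[i0:i1] = ppg_dc + ppg_gain * dpl[::_OVERSAMPLE]
    ecg[r_idx[r_idx < n_samples]] = 1.0
    return ecg, abp, ppg


def _add_noise(record: WaveformRecord, truth: SubjectGroundTruth,
               rng: np.random.Generator) -> None:
    if truth.noise_sd <= 0:
        return
    pp = truth.pulse_pressure
    amp = truth.ppg_gain * pp / truth.baseline_K  # PPG excursion scale
    record.abp += rng.normal(0.0, truth.noise_sd * pp, record.n_samples)
    record.ppg += rng.normal(0.0, truth.noise_sd * amp, record.n_samples)


def generate_beat_record(
    truth: SubjectGroundTruth,
    duration: float,
    sampling_rate: float = DEFAULT_FS,
    seed: int | None = None,
    k_schedule=None,
) -> tuple[WaveformRecord, pd.DataFrame]:
    """Steady-rhythm record with a known per-beat (K, B) schedule.

    ``k_schedule`` may be a callable ``t -> K`` overriding the constant
    baseline stiffness.  Returns the record (R times annotated) and a
    ground-truth table ``beat_time, K, B``.
    """
    fs = sampling_rate
    rr_samples = int(round(fs * 60.0 / truth.hr))
    n_samples = int(round(duration * fs))
    r_idx = np.arange(0, n_samples, rr_samples)
    if len(r_idx) < 2:
        raise ValueError("duration must cover at least 2 beats")
    t_b = r_idx / fs
    K_b = np.array([k_schedule(t) if k_schedule else truth.baseline_K for t in t_b])
    B_b = np.full_like(K_b, truth.baseline_B)
    sys_b = np.full_like(K_b, truth.sbp_baseline)
    dia_b = sys_b - truth.pulse_pressure
    ecg, abp, ppg = _render(fs, r_idx, n_samples, K_b, B_b, sys_b, dia_b,
                            truth.ppg_gain, truth.ppg_dc)
    record = WaveformRecord(fs, ecg, abp, ppg, r_times=t_b)
    _add_noise(record, truth, np.random.default_rng(seed))
    schedule = pd.DataFrame({"beat_time": t_b, "K": K_b, "B": B_b})
    return record, schedule


# ---------------------------------------------------------------------------
# evoked-response dynamics
# ---------------------------------------------------------------------------

def _response_envelope(t: float, stim_times: np.ndarray, magnitudes: np.ndarray) -> float:
    """Fractional response at time t: triangular rise to the peak at
    +10 s, linear return to baseline by +30 s after each stimulus."""
    u = t - stim_times
    active = (u > 0) & (u < RESPONSE_END_S)
    if not active.any():
        return 0.0
    u = u[active]
    m = magnitudes[active]
    tri = np.where(
        u <= RESPONSE_PEAK_S,
        u / RESPONSE_PEAK_S,
        (RESPONSE_END_S - u) / (RESPONSE_END_S - RESPONSE_PEAK_S),
    )
    return float(np.max(m * tri))


def _magnitudes(currents: np.ndarray, threshold: float | None,
                gain: float, sub_pct: float, step: float) -> np.ndarray:
    """Peak fractional change per rung of the ladder."""
    sub = sub_pct / 100.0
    if threshold is None or gain <= 0:
        return np.full(len(currents), sub)
    supra = gain * (currents - threshold + step) / 100.0
    return np.where(currents >= threshold, supra, sub)


def generate_stim_session(
    truth: SubjectGroundTruth,
    start_current: float = 10.0,
    step: float = 10.0,
    max_current: float = 80.0,
    isi: float = 40.0,
    sampling_rate: float = DEFAULT_FS,
    seed: int | None = None,
    lead_in: float = 15.0,
    tail: float = 25.0,
    hr_response_gain: float = 0.0,
) -> tuple[WaveformRecord, pd.DataFrame]:
    """Full graded tetanus-stimulation session.

    One stimulus per rung of the ladder (8 for the standard 10–80 mA
    protocol), at least 30 s apart so each response has decayed before
    the next pre-stimulus window opens.  K and systolic BP rise (and
    PPG amplitude falls) transiently after every rung at or above the
    subject's sympathetic threshold; heart rate responds only when
    ``hr_response_gain`` is positive, mirroring the weak HR responses
    seen clinically.  Returns the record and the stimulus event table.
    """
    if isi < 30.0:
        raise ValueError("inter-stimulus interval must be >= 30 s")
    fs = sampling_rate
    currents = np.arange(start_current, max_current + step / 2, step)
    stim_times = lead_in + isi * np.arange(len(currents))
    duration = lead_in + isi * (len(currents) - 1) + tail
    n_samples = int(round(duration * fs))

    thr = truth.sympathetic_threshold
    mag_main = _magnitudes(currents, thr, truth.response_gain,
                           truth.subthreshold_pct, step)
    mag_hr = _magnitudes(currents, thr, hr_response_gain,
                         truth.subthreshold_pct, step)

    # heart rhythm first (RR depends on the HR response), then per-beat params
    r_idx: list[int] = []
    i = 0
    while i < n_samples:
        r_idx.append(i)
        r_hr = _response_envelope(i / fs, stim_times, mag_hr)
        rr = 60.0 / (truth.hr * (1.0 + r_hr))
        i += max(4, int(round(rr * fs)))
    r_idx = np.asarray(r_idx)
    t_b = r_idx / fs

    resp = np.array([_response_envelope(t, stim_times, mag_main) for t in t_b])
    K_b = truth.baseline_K * (1.0 + resp)
    # viscosity co-varies with stiffness during vasoconstriction, which
    # makes the PPG-amplitude response the exact reciprocal of the K rise
    B_b = truth.baseline_B * (1.0 + resp)
    sys_b = truth.sbp_baseline * (1.0 + resp)
    dia_b = sys_b - truth.pulse_pressure
    ecg, abp, ppg = _render(fs, r_idx, n_samples, K_b, B_b, sys_b, dia_b,
                            truth.ppg_gain, truth.ppg_dc)
    record = WaveformRecord(fs, ecg, abp, ppg, r_times=t_b)
    _add_noise(record, truth, np.random.default_rng(seed))
    events = pd.DataFrame(
        {"event_type": "stimulus", "time": stim_times, "current": currents}
    )
    return record, events


def generate_incision_segment(
    truth: SubjectGroundTruth,
    seed: int | None = None,
    sampling_rate: float = DEFAULT_FS,
    baseline_duration: float = 20.0,
    cautery_delay: float = 25.0,
) -> tuple[WaveformRecord, IncisionWindow]:
    """Skin-incision segment with a programmed systolic-BP ratio.

    Systolic pressure steps to ``sbp_baseline·(1 + rocbp_true/100)`` for
    the whole incision-to-cautery interval and back to baseline after,
    so the measured post/pre ratio equals the programmed one for both
    positive and negative ROC_BP (up to beat quantisation).
    """
    fs = sampling_rate
    t_inc = baseline_duration
    t_cau = t_inc + cautery_delay
    duration = t_cau + 5.0
    n_samples = int(round(duration * fs))
    rr_samples = int(round(fs * 60.0 / truth.hr))
    r_idx = np.arange(0, n_samples, rr_samples)
    t_b = r_idx / fs
    ratio = 1.0 + truth.rocbp_true / 100.0
    sys_b = np.where((t_b > t_inc) & (t_b <= t_cau),
                     truth.sbp_baseline * ratio, truth.sbp_baseline)
    dia_b = sys_b - truth.pulse_pressure
    K_b = np.full_like(sys_b, truth.baseline_K)
    B_b = np.full_like(sys_b, truth.baseline_B)
    ecg, abp, ppg = _render(fs, r_idx, n_samples, K_b, B_b, sys_b, dia_b,
                            truth.ppg_gain, truth.ppg_dc)
    record = WaveformRecord(fs, ecg, abp, ppg, r_times=t_b)
    _add_noise(record, truth, np.random.default_rng(seed))
    return record, IncisionWindow(t_inc, t_cau)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Cohort table of per-subject (MEC, K_R80, ROC_BP) with ground truth.

    Measurable subjects draw MEC_K uniformly on the 10–80 mA ladder and
    ROC_BP from the linear model plus Gaussian noise; an ``oor_fraction``
    of subjects is out of range with low ROC_BP (mean 0.7%).  The other
    MEC columns are jittered versions of MEC_K with realistic
    out-of-range rates (heart rate mostly unmeasurable).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    n_oor = int(round(spec.oor_fraction * n))
    ladder = np.arange(10.0, 90.0, 10.0)

    mec_k = rng.choice(ladder, size=n)
    roc = spec.slope_true * mec_k + spec.intercept_true
    if spec.noise_sd > 0:
        roc = roc + rng.normal(0.0, spec.noise_sd, n)
    oor_ids = rng.choice(n, size=n_oor, replace=False) if n_oor else np.array([], int)
    mec_k_col: list = list(mec_k)
    for i in oor_ids:
        mec_k_col[i] = OUT_OF_RANGE
        roc[i] = 0.7 + (rng.normal(0.0, 2.0) if spec.noise_sd > 0 else 0.0)

    def jitter(p_oor: float) -> list:
        col: list = []
        for i in range(n):
            if rng.random() < p_oor:
                col.append(OUT_OF_RANGE)
            else:
                base = mec_k[i] + 10.0 * rng.integers(-1, 2)
                col.append(float(np.clip(base, 10.0, 80.0)))
        return col

    k_r80 = 20.0 * (roc - 13.25)
    if spec.noise_sd > 0:
        k_r80 = k_r80 + rng.normal(0.0, 4.0 * spec.noise_sd, n)
    cohort = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:02d}" for i in range(n)],
            "mec_k": mec_k_col,
            "mec_hr": jitter(0.73),
            "mec_bp": jitter(0.30),
            "mec_ppg": jitter(0.17),
            "k_r80": k_r80,
            "roc_bp": roc,
        }
    )
    truth = {
        "slope_true": spec.slope_true,
        "intercept_true": spec.intercept_true,
        "noise_sd": spec.noise_sd,
        "oor_subject_ids": [f"S{i + 1:02d}" for i in sorted(oor_ids)],
    }
    return cohort, truth
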