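"""Stimulus-evoked responses, minimum evoked current (MEC) and ROC_BP.

A graded tetanus-stimulation ladder (10 mA steps up to 80 mA) probes
the sympathetic response under constant opioid analgesia.  For each
rung the percent change of a monitored parameter (vascular stiffness K,
heart rate, systolic blood pressure, PPG amplitude) is measured between
a 10 s pre-stimulus window (median) and a 20 s post-stimulus window
(maximum; minimum for PPG amplitude, which responds downward).

The MEC of a parameter is one step above the largest current whose
change stayed at or below 5%; a supra-threshold change at a lower rung
followed by a sub-threshold change later is thereby rejected as noise.
If even 80 mA produces no more-than-5% change the MEC is out of range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: marker for an MEC beyond the maximum stimulator output
OUT_OF_RANGE = "out_of_range"

PARAMETERS = ("K", "HR", "BP", "PPG")
_TRACE_COLUMN = {"K": "K", "HR": "hr", "BP": "sbp", "PPG": "ppg_amp"}
#: parameters whose evoked response is a decrease
_INVERTED = frozenset({"PPG"})

PRE_WINDOW_S = 10.0
POST_WINDOW_S = 20.0
THRESHOLD_PCT = 5.0


class InsufficientDataError(ValueError):
    """A required analysis window contains no valid beats."""


class LadderError(ValueError):
    """The stimulation ladder is incomplete."""


@dataclass(frozen=True)
class StimulusEvent:
    time: float          # seconds
    current: float       # mA


@dataclass(frozen=True)
class IncisionWindow:
    incision_time: float  # seconds
    cautery_time: float   # seconds

    def __post_init__(self) -> None:
        if self.cautery_time <= self.incision_time:
            raise ValueError("cautery_time must follow incision_time")


@dataclass
class ResponseMeasurement:
    parameter: str
    current: float
    pre_value: float
    post_value: float
    change_pct: float    # direction-adjusted: positive = response-direction change


@dataclass
class MECResult:
    parameter: str
    mec: float | str     # mA, or OUT_OF_RANGE
    per_current_changes: dict[float, float]


@dataclass
class ROCBPResult:
    pre_bp: float        # mmHg
    post_bp: float       # mmHg
    roc_bp: float        # percent excess over pre-incision baseline


def _window_values(
    trace: pd.DataFrame, column: str, lo: float, hi: float,
    include_lo: bool, include_hi: bool,
) -> np.ndarray:
    t = trace["beat_time"].to_numpy()
    left = t >= lo if include_lo else t > lo
    right = t <= hi if include_hi else t < hi
    vals = trace.loc[left & right, column].to_numpy(dtype=float)
    return vals[np.isfinite(vals)]


def measure_response(
    trace: pd.DataFrame,
    stim: StimulusEvent,
    parameter: str,
    pre_window: float = PRE_WINDOW_S,
    post_window: float = POST_WINDOW_S,
) -> ResponseMeasurement:
    """Percent change of one parameter evoked by one stimulus.

    pre = median over beats in ``[stim − pre_window, stim)``; post = max
    (min for PPG) over beats in ``(stim, stim + post_window]``.  The
    change is direction-adjusted so that a response-direction change is
    positive for every parameter: ``100·(post/pre − 1)`` for K/HR/BP and
    ``100·(1 − post/pre)`` for PPG amplitude.
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}")
    col = _TRACE_COLUMN[parameter]
    pre_vals = _window_values(trace, col, stim.time - pre_window, stim.time, True, False)
    post_vals = _window_values(trace, col, stim.time, stim.time + post_window, False, True)
    if len(pre_vals) == 0 or len(post_vals) == 0:
        raise InsufficientDataError(
            f"no valid beats in pre/post window of stimulus at {stim.time} s "
            f"for parameter {parameter}"
        )
    pre = float(np.median(pre_vals))
    if pre <= 0:
        raise InsufficientDataError(f"non-positive pre-stimulus value for {parameter}")
    if parameter in _INVERTED:
        post = float(np.min(post_vals))
        change = 100.0 * (1.0 - post / pre)
    else:
        post = float(np.max(post_vals))
        change = 100.0 * (post / pre - 1.0)
    return ResponseMeasurement(parameter, stim.current, pre, post, change)


def detect_mec(
    responses: list[ResponseMeasurement],
    step: float = 10.0,
    max_current: float = 80.0,
    threshold_pct: float = THRESHOLD_PCT,
    start_current: float = 10.0,
) -> MECResult:
    """Minimum evoked current from a full ladder of responses.

    Let c* be the largest current whose change is at or below the
    threshold.  Then MEC = c* + step if c* < max_current; out of range
    if c* = max_current; and the lowest current if every rung exceeded
    the threshold.  This single rule also rejects isolated early
    crossings as noise.
    """
    expected = np.arange(start_current, max_current + step / 2, step)
    by_current = {r.current: r.change_pct for r in responses}
    for c in expected:
        if c not in by_current:
            raise LadderError(f"missing response at {c:g} mA in the stimulation ladder")
    changes = {float(c): float(by_current[c]) for c in expected}
    sub = [c for c, ch in changes.items() if ch <= threshold_pct]
    parameter = responses[0].parameter if responses else "?"
    if not sub:
        mec: float | str = float(start_current)
    elif max(sub) >= max_current:
        mec = OUT_OF_RANGE
    else:
        mec = float(max(sub) + step)
    return MECResult(parameter, mec, changes)


def compute_kr80(
    responses: list[ResponseMeasurement], max_current: float = 80.0
) -> float:
    """Rate of change of K at the maximal stimulus, percent (100 = no change)."""
    for r in responses:
        if r.current == max_current:
            return 100.0 * r.post_value / r.pre_value
    raise LadderError(f"no response at {max_current:g} mA")


def compute_rocbp(
    trace: pd.DataFrame,
    window: IncisionWindow,
    pre_window: float = PRE_WINDOW_S,
) -> ROCBPResult:
    """Rate of change of systolic BP at skin incision.

    pre-BP = median systolic pressure over the 10 s before incision;
    post-BP = maximum systolic pressure between incision and the start
    of electrocautery; ROC_BP = 100·(post/pre − 1), possibly negative.
    """
    ti, tc = window.incision_time, window.cautery_time
    pre_vals = _window_values(trace, "sbp", ti - pre_window, ti, True, False)
    post_vals = _window_values(trace, "sbp", ti, tc, False, False)
    if len(pre_vals) == 0 or len(post_vals) == 0:
        raise InsufficientDataError("no beats in the pre-incision or incision window")
    pre_bp = float(np.median(pre_vals))
    post_bp = float(np.max(post_vals))
    return ROCBPResult(pre_bp, post_bp, 100.0 * (post_bp / pre_bp - 1.0))


def session_mec(
    trace: pd.DataFrame,
    stimuli: list[StimulusEvent],
    parameters: tuple[str, ...] = PARAMETERS,
    step: float = 10.0,
    max_current: float = 80.0,
    threshold_pct: float = THRESHOLD_PCT,
    start_current: float = 10.0,
) -> dict[str, MECResult]:
    """MEC for each monitored parameter over one stimulation session."""
    out: dict[str, MECResult] = {}
    stimuli = sorted(stimuli, key=lambda s: s.current)
    for p in parameters:
        responses = [measure_response(trace, s, p) for s in stimuli]
        out[p] = detect_mec(responses, step, max_current, threshold_pct, start_current)
    return out


def session_kr80(trace: pd.DataFrame, stimuli: list[StimulusEvent],
                 max_current: float = 80.0) -> float:
    """K_R80 for one session: K change ratio at the maximal rung."""
    for s in stimuli:
        if s.current == max_current:
            return compute_kr80([measure_response(trace, s, "K")], max_current)
    raise LadderError(f"no stimulus at {max_current:g} mA in the session")
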