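"""Preprocessing of multi-batch bioreactor recordings.

A repeated-batch evolution experiment produces one continuous multichannel
recording per reactor, sampled on a uniform 15-s grid.  Before the soft
sensor can run, the recording has to be cut into batch / drain / refill
segments, the off-gas channels smoothed and fitted, badly fitted batches
discarded, and slow sensor drift removed:

* segmentation follows the passaging controller's own trigger logic — a
  batch ends at the first upward crossing of the dissolved-oxygen (DO)
  threshold after the minimum batch time, the spike being caused by carbon
  source depletion; refill completion is signalled by the conductivity probe
  re-contacting the medium.  Explicit phase annotations, when present, take
  precedence over signal-based detection.
* each batch's O2 and CO2 off-gas traces are fitted to f(t) = a·e^(b·t) + c
  by nonlinear least squares; batches whose fit has R² below 0.98 are
  discarded.  The first 10 minutes of every batch after the first are
  excluded from fitting (unreliable sensor data right after the reactor
  content exchange), and the fit window ends at the off-gas extremum, i.e.
  at substrate depletion, so the post-depletion signal collapse does not
  distort the fit.
* a baseline correction anchors the fitted curve to the known inflow gas
  concentration, removing additive sensor drift accumulated over days of
  operation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ProcessSeries",
    "BatchSegment",
    "ExponentialFit",
    "moving_average",
    "segment_batches",
    "fit_exponential",
    "quality_gate",
    "baseline_correct",
]

#: Phase labels, matching the three phases of the passaging cycle.
PHASE_BATCH = "batch"
PHASE_DRAIN = "drain"
PHASE_REFILL = "refill"

#: Sampling interval of the data acquisition, seconds.
DEFAULT_DT_S = 15.0


@dataclass
class ProcessSeries:
    """Uniformly sampled multichannel bioreactor recording.

    ``data`` holds one column per channel (``y_o2_pct``, ``y_co2_pct``,
    ``do_pct``, optionally ``ph``, ``conductivity_ms``, ``phase``); ``t`` is
    the sample time in seconds on a strictly increasing uniform grid.
    """

    t: np.ndarray
    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1 or len(self.t) == 0:
            raise ValueError("time vector must be 1-D and non-empty")
        if len(self.t) != len(self.data):
            raise ValueError("time vector and channel table differ in length")
        if len(self.t) > 1:
            steps = np.diff(self.t)
            if np.any(steps <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("timestamps must lie on a uniform grid")

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else DEFAULT_DT_S

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.t)

    def slice(self, i_start: int, i_end: int) -> "ProcessSeries":
        """Sub-series over sample indices [i_start, i_end)."""
        return ProcessSeries(
            t=self.t[i_start:i_end],
            data=self.data.iloc[i_start:i_end].reset_index(drop=True),
            metadata=dict(self.metadata),
        )


@dataclass(frozen=True)
class BatchSegment:
    """One phase segment: half-open sample range [i_start, i_end).

    ``batch_index`` is the 1-based ordinal of the batch the segment belongs
    to (a drain/refill pair carries the index of the batch it terminates).
    ``complete`` is False for a trailing batch that never reached its
    passaging trigger.
    """

    batch_index: int
    i_start: int
    i_end: int
    phase: str = PHASE_BATCH
    complete: bool = True

    def __post_init__(self) -> None:
        if self.i_end <= self.i_start:
            raise ValueError("segment must contain at least one sample")
        if self.phase not in (PHASE_BATCH, PHASE_DRAIN, PHASE_REFILL):
            raise ValueError(f"unknown phase {self.phase!r}")


def moving_average(series, window: int = 6) -> np.ndarray:
    """Trailing moving average with window ``window`` samples.

    The first samples average over however many are available, so the output
    has the same length as the input.  ``window=1`` is the identity.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot smooth an empty series")
    return (
        pd.Series(arr).rolling(window=window, min_periods=1).mean().to_numpy()
    )


def _segments_from_phase_channel(phase: np.ndarray) -> list[BatchSegment]:
    """Cut the recording at phase-label changes (annotation channel)."""
    segments: list[BatchSegment] = []
    batch_idx = 0
    run_start = 0
    n = len(phase)
    for i in range(1, n + 1):
        if i == n or phase[i] != phase[run_start]:
            label = str(phase[run_start])
            if label == PHASE_BATCH:
                batch_idx += 1
            # a trailing batch with no drain after it never reached its trigger
            complete = not (label == PHASE_BATCH and i == n)
            segments.append(
                BatchSegment(
                    batch_index=max(batch_idx, 1),
                    i_start=run_start,
                    i_end=i,
                    phase=label,
                    complete=complete,
                )
            )
            run_start = i
    return segments


def _segments_from_signals(
    series: ProcessSeries,
    do_threshold: float,
    min_batch_time: float,
    conductivity_threshold: float,
    hysteresis: float,
    smooth_window: int,
) -> list[BatchSegment]:
    do = moving_average(series.data["do_pct"].to_numpy(), smooth_window)
    cond = (
        series.data["conductivity_ms"].to_numpy()
        if "conductivity_ms" in series.data
        else None
    )
    n = len(do)
    min_samples = max(int(round(min_batch_time * 3600.0 / series.dt)), 1)

    segments: list[BatchSegment] = []
    batch_idx = 1
    i = 0
    while i < n:
        batch_start = i
        armed = False
        end = None
        j = batch_start + 1
        while j < n:
            if j - batch_start >= min_samples:
                if do[j] <= do_threshold - hysteresis:
                    armed = True
                if armed and do[j] > do_threshold:
                    end = j
                    break
            j += 1
        if end is None:
            segments.append(
                BatchSegment(batch_idx, batch_start, n, PHASE_BATCH, complete=False)
            )
            break
        segments.append(BatchSegment(batch_idx, batch_start, end, PHASE_BATCH))
        # gap: ends at conductivity re-contact (refill complete), else when
        # DO falls back below the threshold (next batch's demand picks up)
        gap_end = None
        k = end + 1
        was_below = False
        while k < n:
            if cond is not None:
                if cond[k] <= conductivity_threshold:
                    was_below = True
                elif was_below:
                    gap_end = k
                    break
            else:
                if do[k] < do_threshold:
                    gap_end = k
                    break
            k += 1
        if gap_end is None:
            mid = end + max((n - end) // 2, 1)
            if mid < n:
                segments.append(BatchSegment(batch_idx, end, mid, PHASE_DRAIN))
                segments.append(BatchSegment(batch_idx, mid, n, PHASE_REFILL))
            else:
                segments.append(BatchSegment(batch_idx, end, n, PHASE_DRAIN))
            break
        # the drain/refill handover is not observable from these channels;
        # split the gap at its midpoint
        mid = end + max((gap_end - end) // 2, 1)
        segments.append(BatchSegment(batch_idx, end, mid, PHASE_DRAIN))
        segments.append(BatchSegment(batch_idx, mid, gap_end, PHASE_REFILL))
        batch_idx += 1
        i = gap_end
    return segments


def segment_batches(
    series: ProcessSeries,
    do_threshold: float = 75.0,
    min_batch_time: float = 1.0,
    conductivity_threshold: float = 200.0,
    *,
    hysteresis: float = 5.0,
    smooth_window: int = 6,
    use_phase_channel: bool = True,
) -> list[BatchSegment]:
    """Cut a multi-batch recording into batch / drain / refill segments.

    An explicit ``phase`` annotation channel, if present, takes precedence.
    Otherwise the passaging trigger is reconstructed from the signals: a
    batch ends at the first sample (after ``min_batch_time`` hours) where the
    smoothed DO exceeds ``do_threshold`` %, *after* the DO has first dropped
    below ``do_threshold − hysteresis`` — the arming step rejects spurious
    noise crossings while the DO descends through the threshold early in the
    batch.  A trailing batch without a trigger is kept and flagged
    ``complete=False``.
    """
    if use_phase_channel and "phase" in series.data:
        return _segments_from_phase_channel(series.data["phase"].to_numpy())
    if "do_pct" not in series.data:
        raise ValueError(
            "segmentation needs a 'phase' annotation channel or a 'do_pct' channel"
        )
    return _segments_from_signals(
        series,
        do_threshold,
        min_batch_time,
        conductivity_threshold,
        hysteresis,
        smooth_window,
    )


@dataclass(frozen=True)
class ExponentialFit:
    """Parameters of f(t) = a·e^(b·(t − t0)) + c and its goodness of fit.

    ``t0`` is the time origin used during fitting (seconds); ``b`` is in
    s⁻¹.  ``r2`` is the coefficient of determination on the fitted samples
    (defined as 0 for zero-variance input).  ``converged`` is False when the
    optimiser failed; such fits fall below any sensible quality gate.
    """

    a: float
    b: float
    c: float
    r2: float
    t0: float = 0.0
    converged: bool = True

    def predict(self, t) -> np.ndarray:
        return self.a * np.exp(self.b * (np.asarray(t, dtype=float) - self.t0)) + self.c


def _r_squared(y, y_hat) -> float:
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 0.0
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


def fit_exponential(t, y) -> ExponentialFit:
    """Least-squares fit of a·e^(b·t)+c to one off-gas batch trace.

    Deterministic initialisation: c ← first sample, a ← last−first sample,
    b ← log-linear slope of |y − c| over the second half of the trace.  A
    non-converging optimisation is reported through the returned fit
    (``converged=False``, R² of the initial guess), never as an exception.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 samples to fit")
    if len(t) != len(y):
        raise ValueError("t and y differ in length")
    t0 = float(t[0])
    tt = t - t0

    if np.ptp(y) == 0.0:
        return ExponentialFit(a=0.0, b=0.0, c=float(y[0]), r2=0.0, t0=t0)

    c0 = float(y[0])
    a0 = float(y[-1] - y[0])
    if a0 == 0.0:
        a0 = float(np.max(y) - np.min(y)) or 1.0
    half = len(y) // 2
    resid = y[half:] - c0
    sign = 1.0 if a0 >= 0 else -1.0
    mag = sign * resid
    mask = mag > max(1e-12, 1e-6 * np.max(np.abs(y)))
    if mask.sum() >= 2:
        slope, _ = np.polyfit(tt[half:][mask], np.log(mag[mask]), 1)
        b0 = float(slope)
    else:
        b0 = 1.0 / max(tt[-1], 1.0)

    p0 = (a0, b0, c0)

    def f(x, a, b, c):
        return a * np.exp(np.clip(b * x, -700, 700)) + c

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(f, tt, y, p0=p0, maxfev=10000)
        a, b, c = (float(v) for v in popt)
        if not all(math.isfinite(v) for v in (a, b, c)):
            raise RuntimeError("non-finite parameters")
        converged = True
    except (RuntimeError, optimize.OptimizeWarning, ValueError):
        a, b, c = p0
        converged = False

    r2 = _r_squared(y, f(tt, a, b, c))
    return ExponentialFit(a=a, b=b, c=c, r2=r2, t0=t0, converged=converged)


def fit_exponential_joint(
    t, y1, y2, init1: ExponentialFit | None = None,
    init2: ExponentialFit | None = None,
) -> tuple[ExponentialFit, ExponentialFit]:
    """Fit two traces to exponentials sharing one rate constant.

    Both off-gas channels of a growing culture are driven by the same
    biomass exponential, so their rate constants are equal up to noise.
    Model: y1 = a1·e^(b·t)+c1, y2 = a2·e^(b·t)+c2 with common b, solved by
    weighted least squares (each channel weighted by the residual scale of
    its independent fit).  Sharing b matters because downstream linear
    combinations of the two reconstructed rates difference two large terms:
    a small mismatch between independently fitted rate constants is
    amplified roughly by the ratio of the individual terms to their
    difference (~8x for typical aerobic stoichiometry).
    """
    t = np.asarray(t, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    f1 = init1 if init1 is not None else fit_exponential(t, y1)
    f2 = init2 if init2 is not None else fit_exponential(t, y2)
    t0 = float(t[0])
    tt = t - t0

    def resid_scale(f, y):
        r = y - f.predict(t)
        s = float(np.std(r))
        return s if s > 0 else 1.0

    s1, s2 = resid_scale(f1, y1), resid_scale(f2, y2)
    b0 = 0.5 * (f1.b + f2.b)

    def residuals(p):
        b, a1, c1, a2, c2 = p
        e = np.exp(np.clip(b * tt, -700, 700))
        return np.concatenate([(a1 * e + c1 - y1) / s1, (a2 * e + c2 - y2) / s2])

    p0 = np.array([b0, f1.a, f1.c, f2.a, f2.c])
    try:
        sol = optimize.least_squares(residuals, p0, method="lm", max_nfev=10000)
        b, a1, c1, a2, c2 = (float(v) for v in sol.x)
        converged = sol.success and all(
            math.isfinite(v) for v in (b, a1, c1, a2, c2)
        )
    except Exception:
        b, a1, c1, a2, c2 = (float(v) for v in p0)
        converged = False
    if not converged:
        return f1, f2
    e = np.exp(np.clip(b * tt, -700, 700))
    out1 = ExponentialFit(a=a1, b=b, c=c1, r2=_r_squared(y1, a1 * e + c1), t0=t0)
    out2 = ExponentialFit(a=a2, b=b, c=c2, r2=_r_squared(y2, a2 * e + c2), t0=t0)
    return out1, out2


def quality_gate(fit: ExponentialFit, threshold: float = 0.98) -> bool:
    """Keep (True) a fit whose R² reaches ``threshold``; boundary inclusive."""
    return fit.converged and fit.r2 >= threshold


def baseline_correct(
    fit: ExponentialFit,
    inflow: float,
    *,
    anchor: str = "baseline",
) -> ExponentialFit:
    """Shift a fitted off-gas curve so it is anchored to the inflow level.

    For an exponentially growing culture the off-gas trace is
    y_in ± β·e^(μt): its additive offset ``c`` equals the inflow
    concentration, so any deviation of ``c`` from the inflow measures
    additive sensor drift.  ``anchor="baseline"`` (default) therefore shifts
    the curve by ``c − inflow``.  ``anchor="start"`` instead forces the
    fitted value at the batch start to the inflow level, f(t) − (f(t0) −
    inflow); this also cancels the (small but real) gas conversion of the
    inoculum, which biases the downstream growth-rate estimate upward, and is
    provided for comparison only.

    The shift is additive, so the growth-relevant rate constant ``b`` is
    preserved.  Units of ``inflow`` must match the fitted channel (percent
    for the standard pipeline).
    """
    if anchor == "baseline":
        shift = fit.c - inflow
    elif anchor == "start":
        shift = (fit.a + fit.c) - inflow
    else:
        raise ValueError("anchor must be 'baseline' or 'start'")
    return replace(fit, c=fit.c - shift)
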