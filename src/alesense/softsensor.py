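"""Per-batch biomass/substrate trajectories and growth-rate estimation.

The off-gas balance yields volumetric C-mole conversion rates rx (biomass
formation) and rs (substrate consumption) at every sample.  Integrating them
by the trapezoidal rule and scaling by the C-mole molar masses gives
concentration trajectories,

    cx(t) = cx0 + Mx · ∫ rx dt        cs(t) = s0 − Ms · ∫ rs dt ,

and the specific growth rate μ is the least-squares slope of ln cx over the
final part of the batch, which skips the lag and transition phases.  Because
μ is a log-slope it is invariant to rescaling cx, so an imprecise inoculum
concentration cx0 barely affects it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "BatchEstimate",
    "integrate_biomass",
    "integrate_substrate",
    "estimate_growth_rate",
    "depletion_index",
]


@dataclass
class BatchEstimate:
    """Soft-sensor output for one batch.

    t is batch-relative time in hours; cx and cs are biomass and substrate
    concentrations in g L⁻¹; mu_hat is the specific growth rate in h⁻¹ with
    the R² of its log-linear fit; duration is the analysed batch length in
    hours and window_fraction the trailing fraction of it used for μ.
    """

    batch_index: int
    t: np.ndarray
    cx: np.ndarray
    cs: np.ndarray
    mu_hat: float
    mu_fit_r2: float
    duration: float
    window_fraction: float
    kept: bool = True
    complete: bool = True
    diagnostics: dict = field(default_factory=dict)

    @property
    def cx_end(self) -> float:
        """Biomass concentration at the end of the exponential phase."""
        idx = self.diagnostics.get("depletion_idx")
        return float(self.cx[idx if idx is not None else -1])

    @property
    def cx_start(self) -> float:
        return float(self.cx[0])


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("time vector must be 1-D with >= 2 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time vector must be strictly increasing")
    return t


def integrate_biomass(t, rx, cx0: float, mx: float) -> np.ndarray:
    """Biomass trajectory from the volumetric formation rate.

    cx(t_k) = cx0 + mx·trapezoid(rx, t) cumulatively, with t in hours, rx in
    C-mol L⁻¹ h⁻¹ and mx in g per C-mol.  Negative rx samples (sensor
    artifacts) integrate as-is.
    """
    t = _check_time(t)
    rx = np.asarray(rx, dtype=float)
    if not np.all(np.isfinite(rx)):
        raise ValueError("rx must be finite")
    if cx0 <= 0:
        raise ValueError("cx0 must be > 0")
    return cx0 + mx * cumulative_trapezoid(rx, t, initial=0.0)


def integrate_substrate(t, rs, s0: float, ms: float) -> np.ndarray:
    """Substrate trajectory cs(t_k) = s0 − ms·trapezoid(rs, t) cumulatively.

    Values may cross zero near depletion; they are reported, not clipped —
    use :func:`depletion_index` to locate the crossing.
    """
    t = _check_time(t)
    rs = np.asarray(rs, dtype=float)
    if s0 <= 0:
        raise ValueError("s0 must be > 0")
    return s0 - ms * cumulative_trapezoid(rs, t, initial=0.0)


def depletion_index(cs) -> int | None:
    """Index of the first sample at or below zero substrate, or None."""
    hits = np.flatnonzero(np.asarray(cs, dtype=float) <= 0.0)
    return int(hits[0]) if hits.size else None


def estimate_growth_rate(t, cx, window_fraction: float = 0.5) -> tuple[float, float]:
    """Specific growth rate from the trailing part of the batch.

    Least-squares slope of ln(cx) against t (hours) over the final
    ``window_fraction`` of the batch, returned with the R² of that linear
    fit.  The default window of 0.5 excludes lag and transition phases; 0.6
    is a common alternative.
    """
    t = _check_time(t)
    cx = np.asarray(cx, dtype=float)
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must lie in (0, 1]")
    t_cut = t[-1] - window_fraction * (t[-1] - t[0])
    mask = t >= t_cut
    if mask.sum() < 4:
        raise ValueError("growth-rate window holds fewer than 4 samples")
    tw, cw = t[mask], cx[mask]
    if np.any(cw <= 0):
        raise ValueError("cx must be positive throughout the growth-rate window")
    log_c = np.log(cw)
    slope, intercept = np.polyfit(tw, log_c, 1)
    fitted = slope * tw + intercept
    ss_tot = float(np.sum((log_c - log_c.mean()) ** 2))
    r2 = 1.0 - float(np.sum((log_c - fitted) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2
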