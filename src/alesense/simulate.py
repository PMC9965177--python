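"""Mechanistic repeated-batch ALE process simulator.

Generates a continuous multichannel recording of a serially passaged batch
culture in a stirred-tank bioreactor, together with the underlying ground
truth, so that every analysis stage can be tested end-to-end without an
instrument.  Per batch the model integrates Monod growth with a lag factor,

    dcx/dt = μ_eff·cx ,   dcs/dt = −μ_eff·cx / Y_xs ,
    μ_eff  = μ_batch · cs/(Ks + cs) · (1 − e^(−t/τ_lag)) ,

by fixed-step 4th-order Runge-Kutta on the 15-s sampling grid.  The true
volumetric conversion rates follow from the exact stoichiometric balance
model, off-gas mole fractions from inverting the inert-gas balance (with a
first-order gas-phase/analyzer lag), and dissolved oxygen from a kLa-based
transfer balance whose stirrer-cascade controller holds DO at a setpoint
while demand allows — reproducing the characteristic DO spike at carbon
depletion that triggers passaging.

Across batches the per-batch growth rate approaches a stable phenotype
exponentially, the lag phase shrinks geometrically, and drain/refill gaps of
realistic duration separate the batches; the refill restores fresh medium
and an inoculum concentration with run-to-run jitter.  Sensor noise, a slow
additive drift of the gas sensors, and the CO2-stripping transient at the
start of every batch after the first complete the measurement model.

Evolution is modelled phenomenologically (deterministic exponential approach
of μ to its ceiling): this is a test harness for the analytics, not a
population-genetic claim.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .offgas import GasSpec, invert_rates
from .preprocess import PHASE_BATCH, PHASE_DRAIN, PHASE_REFILL, ProcessSeries
from .stoichiometry import RateModel, ecoli_glycerol_model

__all__ = ["SimConfig", "SimOutput", "BatchState", "simulate_batch", "simulate_run"]


class SimulationConfigError(ValueError):
    """Raised when a configuration cannot produce a valid passaging cycle."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a repeated-batch ALE simulation.

    Growth-rate evolution: per-batch μ approaches ``mu_stable`` from
    ``mu_init`` with e-folding time ``tau_adapt`` batches; the lag-phase time
    constant starts at ``lag0`` hours and shrinks by ``lag_decay`` per batch.
    Kinetics (Monod constant ``ks``, yield ``y_xs``) are literature-typical
    for E. coli on glycerol.  Process set-points mirror the automated
    passaging cycle: 15 g L⁻¹ glycerol, 0.2 g L⁻¹ inoculum target (lognormal
    jitter ``cx0_jitter_sd``), DO trigger threshold 75 % after a 1-h minimum
    batch time, and a drain/refill exchange of 42.22 ± 3.86 min.
    """

    # evolution of the growth phenotype
    mu_init: float = 0.30
    mu_stable: float = 0.61
    tau_adapt: float = 5.0
    lag0: float = 2.2
    lag_decay: float = 0.7
    # batch kinetics
    ks: float = 0.01
    y_xs: float = 0.45
    s0: float = 15.0
    cx0: float = 0.2
    cx0_jitter_sd: float = 0.2
    # oxygen transfer and DO control
    kla_min: float = 60.0
    kla_max: float = 1200.0
    do_star: float = 100.0
    do_setpoint: float = 30.0
    c_o2_sat: float = 2.5e-4
    # passaging trigger
    do_threshold: float = 75.0
    do_hysteresis: float = 5.0
    min_batch_time: float = 1.0
    max_batch_time: float = 24.0
    exchange_minutes_mean: float = 42.22
    exchange_minutes_sd: float = 3.86
    # run shape
    n_batches: int = 22
    dt: float = 15.0
    gas: GasSpec = field(default_factory=GasSpec)
    gas_lag_s: float = 30.0
    # measurement model
    noise_o2_pct: float = 0.02
    noise_co2_pct: float = 0.01
    noise_do_pct: float = 0.5
    noise_ph: float = 0.01
    noise_cond_ms: float = 1.0
    drift_step_pct: float = 0.005
    co2_spike_pct: float = 0.25
    co2_spike_tau_min: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_init > self.mu_stable:
            raise SimulationConfigError("mu_init must be <= mu_stable")
        for name in (
            "mu_init", "mu_stable", "tau_adapt", "ks", "y_xs", "s0", "cx0",
            "kla_min", "kla_max", "do_star", "c_o2_sat", "min_batch_time",
            "max_batch_time", "exchange_minutes_mean", "dt",
        ):
            if getattr(self, name) <= 0:
                raise SimulationConfigError(f"{name} must be > 0")
        if self.n_batches < 1:
            raise SimulationConfigError("n_batches must be >= 1")
        if not 0 < self.do_setpoint < self.do_threshold - self.do_hysteresis:
            raise SimulationConfigError(
                "DO setpoint must lie below the trigger arming level"
            )

    def noiseless(self) -> "SimConfig":
        """Copy with all stochastic measurement effects switched off."""
        return replace(
            self,
            noise_o2_pct=0.0,
            noise_co2_pct=0.0,
            noise_do_pct=0.0,
            noise_ph=0.0,
            noise_cond_ms=0.0,
            drift_step_pct=0.0,
            co2_spike_pct=0.0,
            cx0_jitter_sd=0.0,
            exchange_minutes_sd=0.0,
        )

    def mu_batch(self, i: int) -> float:
        """True growth-rate ceiling of batch ``i`` (1-based)."""
        return self.mu_stable - (self.mu_stable - self.mu_init) * math.exp(
            -i / self.tau_adapt
        )

    def tau_lag_batch(self, i: int) -> float:
        """Lag-phase time constant (h) of batch ``i`` (1-based)."""
        return self.lag0 * self.lag_decay ** (i - 1)


@dataclass
class BatchState:
    """Carry-over state between consecutive batches of one run."""

    batch_index: int = 1
    cx0: float = 0.2
    do: float = 100.0
    our_gas: float = 0.0
    cer_gas: float = 0.0
    drift_o2_pct: float = 0.0
    drift_co2_pct: float = 0.0
    t_offset_s: float = 0.0


@dataclass
class SimOutput:
    """Simulated recording plus ground truth.

    ``series`` carries the sensor channels (with phase annotations);
    ``truth`` the per-sample state (cx, cs in g L⁻¹, mu in h⁻¹, rx and the
    gas-side our/cer in (C-)mol L⁻¹ h⁻¹ — our/cer are the rates carried by
    the off-gas stream, i.e. after the gas-phase lag, which is what the
    inert-gas balance measures); ``batches`` one row of truth per batch.
    """

    series: ProcessSeries
    truth: pd.DataFrame
    batches: pd.DataFrame
    config: SimConfig


_CHANNELS = ["do_pct", "ph", "y_o2_pct", "y_co2_pct", "conductivity_ms", "phase"]
_TRUTH_COLS = ["cx", "cs", "mu", "rx", "our", "cer", "our_bio", "cer_bio"]

#: conductivity readings (opaque sensor units) for probe-in-medium vs dry
_COND_WET = 230.0
_COND_DRY = 5.0
_PH_SET = 7.0


def _check_trigger_reachable(cfg: SimConfig, model: RateModel) -> None:
    """Fail fast if the culture can never arm the DO trigger."""
    cx_end = cfg.cx0 + cfg.y_xs * cfg.s0
    rx_g = cfg.mu_init * cx_end
    rx_c = rx_g / model.mx
    rs_c = (rx_g / cfg.y_xs) / model.ms
    cer = rs_c - rx_c
    our_peak = (rx_c - model.a_xc * cer) / model.a_xo
    alpha = cfg.do_star / cfg.c_o2_sat
    kla_req = alpha * our_peak / (cfg.do_star - cfg.do_setpoint)
    if kla_req < cfg.kla_min:
        dip = alpha * our_peak / cfg.kla_min
        if cfg.do_star - dip > cfg.do_threshold - cfg.do_hysteresis:
            raise SimulationConfigError(
                "peak oxygen demand too small to pull DO below the trigger "
                "arming level; increase s0, cx0 or decrease kla_min"
            )


def _rates_from_state(cfg: SimConfig, model: RateModel, mu_eff: float, cx: float):
    """True (rx_c, our, cer) in C-mole units from the biological state."""
    rx_g = mu_eff * cx
    rx_c = rx_g / model.mx
    rs_c = (rx_g / cfg.y_xs) / model.ms
    cer = rs_c - rx_c
    our = (rx_c - model.a_xc * cer) / model.a_xo
    return rx_c, our, cer


def _rk4_step(cfg: SimConfig, mu_batch: float, tau_lag: float, t_h: float,
              cx: float, cs: float, dt_h: float):
    def deriv(t, x, s):
        s_pos = max(s, 0.0)
        lag = 1.0 - math.exp(-t / tau_lag) if tau_lag > 0 else 1.0
        mu = mu_batch * (s_pos / (cfg.ks + s_pos)) * lag
        dx = mu * x
        return dx, -dx / cfg.y_xs

    k1x, k1s = deriv(t_h, cx, cs)
    k2x, k2s = deriv(t_h + dt_h / 2, cx + dt_h / 2 * k1x, cs + dt_h / 2 * k1s)
    k3x, k3s = deriv(t_h + dt_h / 2, cx + dt_h / 2 * k2x, cs + dt_h / 2 * k2s)
    k4x, k4s = deriv(t_h + dt_h, cx + dt_h * k3x, cs + dt_h * k3s)
    cx_new = cx + dt_h / 6 * (k1x + 2 * k2x + 2 * k3x + k4x)
    cs_new = cs + dt_h / 6 * (k1s + 2 * k2s + 2 * k3s + k4s)
    return cx_new, max(cs_new, 0.0)


class _Recorder:
    """Accumulates per-sample channel and truth rows."""

    def __init__(self) -> None:
        self.rows: dict[str, list] = {c: [] for c in _CHANNELS + _TRUTH_COLS}
        self.t_s: list[float] = []

    def add(self, t_s, channels: dict, truth: dict) -> None:
        self.t_s.append(t_s)
        for c in _CHANNELS:
            self.rows[c].append(channels[c])
        for c in _TRUTH_COLS:
            self.rows[c].append(truth[c])


def _emit_sample(cfg, model, rec, state: BatchState, rng, *, t_s, phase,
                 cx, cs, mu_eff, co2_spike_pct=0.0):
    """Advance gas/DO states by one sample and record it."""
    dt_h = cfg.dt / 3600.0
    rx_c, our_b, cer_b = _rates_from_state(cfg, model, mu_eff, cx)

    # first-order gas-phase / analyzer lag
    if cfg.gas_lag_s > 0:
        decay = math.exp(-cfg.dt / cfg.gas_lag_s)
        state.our_gas = our_b + (state.our_gas - our_b) * decay
        state.cer_gas = cer_b + (state.cer_gas - cer_b) * decay
    else:
        state.our_gas, state.cer_gas = our_b, cer_b

    # DO transfer balance with stirrer-cascade control of kLa
    alpha = cfg.do_star / cfg.c_o2_sat
    kla_req = alpha * our_b / (cfg.do_star - cfg.do_setpoint)
    kla_eff = min(max(kla_req, cfg.kla_min), cfg.kla_max)
    do_ss = cfg.do_star - alpha * our_b / kla_eff
    state.do = do_ss + (state.do - do_ss) * math.exp(-kla_eff * dt_h)

    y_o2, y_co2 = invert_rates(state.our_gas, state.cer_gas, cfg.gas)
    do_meas = state.do + (rng.normal(0.0, cfg.noise_do_pct) if cfg.noise_do_pct else 0.0)
    in_batch = phase == PHASE_BATCH
    channels = {
        "do_pct": do_meas,
        "ph": _PH_SET + (rng.normal(0.0, cfg.noise_ph) if cfg.noise_ph else 0.0),
        "y_o2_pct": y_o2 * 100.0 + state.drift_o2_pct
        + (rng.normal(0.0, cfg.noise_o2_pct) if cfg.noise_o2_pct else 0.0),
        "y_co2_pct": y_co2 * 100.0 + state.drift_co2_pct + co2_spike_pct
        + (rng.normal(0.0, cfg.noise_co2_pct) if cfg.noise_co2_pct else 0.0),
        "conductivity_ms": (_COND_WET if in_batch else _COND_DRY)
        + (rng.normal(0.0, cfg.noise_cond_ms) if cfg.noise_cond_ms else 0.0),
        "phase": phase,
    }
    truth = {
        "cx": cx if in_batch else math.nan,
        "cs": cs if in_batch else math.nan,
        "mu": mu_eff,
        "rx": rx_c,
        "our": state.our_gas,
        "cer": state.cer_gas,
        "our_bio": our_b,
        "cer_bio": cer_b,
    }
    rec.add(t_s, channels, truth)
    return do_meas


def _run_batch(cfg: SimConfig, model: RateModel, rec: _Recorder,
               state: BatchState, rng) -> dict:
    """Simulate one batch until the DO trigger (or the max-time guard)."""
    mu_b = cfg.mu_batch(state.batch_index)
    tau_lag = cfg.tau_lag_batch(state.batch_index)
    dt_h = cfg.dt / 3600.0
    min_steps = max(int(round(cfg.min_batch_time * 3600.0 / cfg.dt)), 1)
    max_steps = int(round(cfg.max_batch_time * 3600.0 / cfg.dt))
    spike_tau_h = cfg.co2_spike_tau_min / 60.0

    i_start = len(rec.t_s)
    cx, cs = state.cx0, cfg.s0
    armed = False
    complete = True
    depletion_k = None
    k = 0
    while True:
        t_rel = k * dt_h
        s_pos = max(cs, 0.0)
        lag = 1.0 - math.exp(-t_rel / tau_lag) if tau_lag > 0 else 1.0
        mu_eff = mu_b * (s_pos / (cfg.ks + s_pos)) * lag
        spike = 0.0
        if state.batch_index >= 2 and cfg.co2_spike_pct:
            spike = cfg.co2_spike_pct * math.exp(-t_rel / spike_tau_h)
        do_meas = _emit_sample(
            cfg, model, rec, state, rng,
            t_s=state.t_offset_s + k * cfg.dt,
            phase=PHASE_BATCH, cx=cx, cs=cs, mu_eff=mu_eff,
            co2_spike_pct=spike,
        )
        if depletion_k is None and cs <= max(1e-3 * cfg.s0, 1e-9):
            depletion_k = k
        if k >= min_steps:
            if armed and do_meas > cfg.do_threshold:
                break
            if do_meas <= cfg.do_threshold - cfg.do_hysteresis:
                armed = True
        if k >= max_steps:
            warnings.warn(
                f"batch {state.batch_index}: DO trigger not reached within "
                f"{cfg.max_batch_time} h; truncating",
                stacklevel=2,
            )
            complete = False
            break
        cx, cs = _rk4_step(cfg, mu_b, tau_lag, t_rel, cx, cs, dt_h)
        k += 1

    n = k + 1
    state.t_offset_s += n * cfg.dt
    return {
        "batch": state.batch_index,
        "mu_batch": mu_b,
        "tau_lag_h": tau_lag,
        "i_start": i_start,
        "i_end": i_start + n,
        "depletion_i": i_start + depletion_k if depletion_k is not None else -1,
        "t_start_h": rec.t_s[i_start] / 3600.0,
        "duration_h": n * cfg.dt / 3600.0,
        "cx0": state.cx0,
        "cx_end": cx,
        "complete": complete,
    }


def _run_gap(cfg: SimConfig, model: RateModel, rec: _Recorder,
             state: BatchState, rng) -> None:
    """Drain/refill gap: no biology, gas washes out, DO recovers."""
    dur_min = cfg.exchange_minutes_mean
    if cfg.exchange_minutes_sd > 0:
        dur_min = rng.normal(cfg.exchange_minutes_mean, cfg.exchange_minutes_sd)
    dur_min = max(dur_min, 5.0)
    n = max(int(round(dur_min * 60.0 / cfg.dt)), 2)
    n_drain = n // 2
    for k in range(n):
        phase = PHASE_DRAIN if k < n_drain else PHASE_REFILL
        _emit_sample(
            cfg, model, rec, state, rng,
            t_s=state.t_offset_s + k * cfg.dt,
            phase=phase, cx=0.0, cs=0.0, mu_eff=0.0,
        )
    state.t_offset_s += n * cfg.dt


def _build_output(cfg: SimConfig, rec: _Recorder, batch_rows: list[dict]) -> SimOutput:
    t = np.asarray(rec.t_s, dtype=float)
    data = pd.DataFrame({c: rec.rows[c] for c in _CHANNELS})
    truth = pd.DataFrame({c: rec.rows[c] for c in _TRUTH_COLS})
    series = ProcessSeries(t=t, data=data, metadata={"generator": "alesense.simulate"})
    batches = pd.DataFrame(batch_rows)
    return SimOutput(series=series, truth=truth, batches=batches, config=cfg)


def simulate_batch(cfg: SimConfig, state: BatchState | None = None,
                   rng: np.random.Generator | None = None) -> SimOutput:
    """Simulate a single batch from the given carry-over state.

    With the default state this is a fresh first batch; callers chaining
    batches manually pass the mutated state back in.
    """
    model = ecoli_glycerol_model()
    _check_trigger_reachable(cfg, model)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if state is None:
        state = BatchState(cx0=cfg.cx0, do=cfg.do_star)
    rec = _Recorder()
    row = _run_batch(cfg, model, rec, state, rng)
    return _build_output(cfg, rec, [row])


def simulate_run(cfg: SimConfig) -> SimOutput:
    """Simulate a full repeated-batch evolution run.

    Chains ``n_batches`` batches separated by drain/refill gaps; per batch
    the growth-rate ceiling rises and the lag shrinks according to the
    configured adaptation law.  Deterministic for a fixed ``cfg.seed``.
    """
    model = ecoli_glycerol_model()
    _check_trigger_reachable(cfg, model)
    rng = np.random.default_rng(cfg.seed)
    state = BatchState(cx0=cfg.cx0, do=cfg.do_star)
    rec = _Recorder()
    rows = []
    for i in range(1, cfg.n_batches + 1):
        state.batch_index = i
        row = _run_batch(cfg, model, rec, state, rng)
        rows.append(row)
        # the cycle always drains after the trigger; the run is stopped
        # during the final exchange, so the recording ends on a gap
        if row["complete"]:
            _run_gap(cfg, model, rec, state, rng)
        if i < cfg.n_batches:
            jitter = (
                rng.lognormal(0.0, cfg.cx0_jitter_sd) if cfg.cx0_jitter_sd else 1.0
            )
            state.cx0 = cfg.cx0 * jitter
            if cfg.drift_step_pct:
                state.drift_o2_pct += rng.normal(0.0, cfg.drift_step_pct)
                state.drift_co2_pct += rng.normal(0.0, cfg.drift_step_pct)
    return _build_output(cfg, rec, rows)
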