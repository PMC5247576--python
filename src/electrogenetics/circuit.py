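"""Charge-dependent reporter expression with ssrA degradation.

The device's genetic output is a fluorescent reporter (phiLOV, DAS-tagged)
expressed from the PsoxS promoter.  Pyocyanin initiates SoxR-mediated
induction; the oxidized mediator Fcn(O) — but not the reduced form —
amplifies it in a dose-dependent way.  The ssrA tag gives the reporter a
short half-life, which enables the 'OFF' dynamics.

Model
-----
Protein (= fluorescence, in arbitrary units) follows

    dP/dt = s(f) - k_deg * P
    s(f)  = pyo/(K_pyo + pyo) * (s0 + s_max * f / (K_fcn + f))

where ``f`` is the oxidized fraction of the mediator pool produced by the
electrolysis model.  The intracellular pyocyanin redox-cycling chemistry is
lumped into the saturating amplification term.

Deconvolution
-------------
Because degradation is first-order, the cumulative degradation-free
synthesis is recoverable from a fluorescence time series alone:

    S(t) = P(t) - P(0) + k_deg * \\int_0^t P dtau

``integrated_synthesis`` implements this identity (trapezoid rule); it is
exactly the inverse of the degradation operator and is what the device's
charge-synthesis linearity is stated in terms of.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.integrate import cumulative_trapezoid

from .electrochem import (
    F_CONST,
    FERRICYANIDE,
    CurrentTrace,
    ElectrolysisState,
    RedoxCouple,
    SignalSchedule,
    integrate_charge,
    nernst_fraction,
    nernst_potential,
)

#: Conventional oxidizing ('ON') and reducing ('OFF') potentials, V vs Ag/AgCl.
ON_POTENTIAL = 0.5
OFF_POTENTIAL = -0.3


@dataclass
class CircuitParams:
    """Parameters of the synthesis/degradation model.

    Defaults are calibration choices, not measured constants: the basal
    plateau sits ~300 au above baseline and the fully amplified plateau is
    ~17x basal (the observed fold-amplification); ``K_fcn = 1`` keeps the
    dose response near-linear over partial pool conversions; ``k_deg``
    corresponds to a 25-min reporter half-life, consistent with visible
    decay within 45 min of an 'OFF' switch.
    """

    s0: float = 0.17          # basal synthesis rate at saturating Pyo, au/s
    s_max: float = 5.44       # maximal Fcn(O)-amplified synthesis rate, au/s
    K_fcn: float = 1.0        # half-saturation oxidized fraction
    pyo: float = 5.0          # pyocyanin concentration, uM
    K_pyo: float = 1.0        # pyocyanin half-saturation, uM
    k_deg: float = math.log(2) / 1500.0   # ssrA degradation rate, 1/s
    maturation_lag: float = 0.0           # s; phiLOV needs no O2 maturation

    def __post_init__(self) -> None:
        for name in ("s0", "s_max", "pyo", "K_pyo", "k_deg", "maturation_lag"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 < self.K_fcn <= 1.0:
            raise ValueError("K_fcn must lie in (0, 1]")


@dataclass
class ExpressionTrace:
    """Reporter fluorescence time series (times s, fluorescence au >= 0)."""

    times: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.shape != self.fluorescence.shape or self.times.ndim != 1:
            raise ValueError("times and fluorescence must be 1-D and equally long")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.fluorescence < 0):
            raise ValueError("fluorescence must be nonnegative")


@dataclass(frozen=True)
class CycleResult:
    """Fluorescence at the half-cycle ('ON' phase end) and cycle end."""

    cycle_time: float
    half_cycle_fluor: float
    end_cycle_fluor: float


@dataclass
class ElectroConfig:
    """Bundle of electrolysis settings shared by expression simulations."""

    state: ElectrolysisState = field(default_factory=ElectrolysisState)
    couple: RedoxCouple = FERRICYANIDE
    k_e: float = math.log(100.0) / 900.0
    k_cell: float = 0.0
    cell_density: float = 0.0
    dt: float = 1.0


@dataclass
class ExpressionResult:
    """Joint output of an expression simulation."""

    trace: ExpressionTrace
    current: CurrentTrace
    frac_ox: np.ndarray
    true_synthesis: np.ndarray   # internally accumulated integral of s(f(t))

    @property
    def times(self) -> np.ndarray:
        return self.trace.times

    @property
    def total_charge(self) -> float:
        return float(integrate_charge(self.current)[-1])


def synthesis_rate(frac_ox: float, params: CircuitParams) -> float:
    """Instantaneous reporter synthesis rate (au/s) at a given oxidized
    fraction of the mediator pool.  Zero without pyocyanin."""
    if not 0.0 <= frac_ox <= 1.0:
        raise ValueError("frac_ox must lie in [0, 1]")
    pyo_term = params.pyo / (params.K_pyo + params.pyo) if params.pyo > 0 else 0.0
    return pyo_term * (params.s0 + params.s_max * frac_ox / (params.K_fcn + frac_ox))


def simulate_expression(
    schedule: SignalSchedule,
    params: CircuitParams | None = None,
    electro: ElectroConfig | None = None,
    P0: float = 0.0,
) -> ExpressionResult:
    """Couple bulk electrolysis to reporter synthesis/degradation.

    Integrates the joint system (f, P, S) with fixed-step RK4 on the
    electrolysis grid, where ``S`` accumulates the synthesis rate and serves
    as the internal ground truth for deconvolution checks.  Deterministic.
    """
    params = params or CircuitParams()
    electro = electro or ElectroConfig()
    if P0 < 0:
        raise ValueError("P0 must be nonnegative")

    st = electro.state
    nfvc = electro.couple.n * F_CONST * st.total_moles
    sink = electro.k_cell * electro.cell_density
    k = params.k_deg

    times = [0.0]
    fracs = [st.frac_ox]
    Ps = [P0]
    Ss = [0.0]
    currents = []

    def syn(f: float) -> float:
        fc = min(max(f, 0.0), 1.0)
        return synthesis_rate(fc, params)

    t = 0.0
    f, P, S = st.frac_ox, P0, 0.0

    first_E = schedule.segments[0][0]
    f_eq0 = None if first_E is None else nernst_fraction(first_E, electro.couple, st.temperature)
    currents.append(0.0 if f_eq0 is None else -nfvc * electro.k_e * (f_eq0 - f))

    from .electrochem import _segment_grid

    for seg_idx, (E, dur) in enumerate(schedule.segments):
        f_eq = None if E is None else nernst_fraction(E, electro.couple, st.temperature)
        a = 0.0 if f_eq is None else electro.k_e * f_eq
        b = (0.0 if f_eq is None else electro.k_e) + sink

        def deriv(y):
            fy, Py, _ = y
            df = a - b * fy
            s = syn(fy)
            return np.array([df, s - k * Py, s])

        if seg_idx > 0:
            eps = 1e-6
            t += eps
            dur -= eps
            times.append(t)
            fracs.append(f)
            Ps.append(P)
            Ss.append(S)
            currents.append(0.0 if f_eq is None else -nfvc * electro.k_e * (f_eq - f))

        nsteps, h = _segment_grid(dur, electro.dt)
        y = np.array([f, P, S])
        for _ in range(nsteps):
            k1 = deriv(y)
            k2 = deriv(y + 0.5 * h * k1)
            k3 = deriv(y + 0.5 * h * k2)
            k4 = deriv(y + h * k3)
            y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
            f, P, S = y
            times.append(t)
            fracs.append(f)
            Ps.append(max(P, 0.0))
            Ss.append(S)
            currents.append(0.0 if f_eq is None else -nfvc * electro.k_e * (f_eq - f))

    times_arr = np.array(times)
    P_arr = np.array(Ps)
    if params.maturation_lag > 0:
        # observed fluorescence is the protein level delayed by the
        # maturation lag (zero-order hold before the lag elapses)
        P_arr = np.interp(times_arr - params.maturation_lag, times_arr, P_arr,
                          left=P0)
    trace = ExpressionTrace(times=times_arr, fluorescence=P_arr)
    current = CurrentTrace(times=times_arr, currents=np.array(currents))
    return ExpressionResult(trace=trace, current=current,
                            frac_ox=np.array(fracs),
                            true_synthesis=np.array(Ss))


def integrated_synthesis(trace: ExpressionTrace, k_deg: float,
                         smooth_window: int | None = None) -> np.ndarray:
    """Degradation-free cumulative synthesis recovered from fluorescence.

    ``S(t) = P(t) - P(0) + k_deg * cumtrapz(P)``.  With the true ``k_deg``
    this inverts first-order degradation exactly (up to quadrature error).

    Measured fluorescence enters the identity pointwise, so measurement
    noise passes straight into S; for noisy data set ``smooth_window`` to
    pre-filter the trace with a centred moving average of that many samples
    (the conventional moving-window time average for fluorescence series)
    before inverting.
    """
    if k_deg < 0:
        raise ValueError("k_deg must be nonnegative")
    if trace.times.size < 2:
        raise ValueError("need at least 2 samples")
    P = trace.fluorescence
    if smooth_window and smooth_window > 1:
        h = smooth_window // 2
        P = np.array([P[max(0, i - h): i + h + 1].mean()
                      for i in range(P.size)])
    integral = cumulative_trapezoid(P, trace.times, initial=0.0)
    return P - P[0] + k_deg * integral


def duration_for_charge(
    target_charge: float,
    electro: ElectroConfig | None = None,
    potential: float = ON_POTENTIAL,
) -> float:
    """Duration of a constant-potential application that delivers a target
    charge (coulombs, negative for oxidation).  Assumes no cell-mediated
    re-reduction during the application.

    Raises if the magnitude exceeds the Faraday maximum of the pool at that
    potential.
    """
    electro = electro or ElectroConfig()
    st = electro.state
    nfvc = electro.couple.n * F_CONST * st.total_moles
    delta_f = abs(target_charge) / nfvc
    if delta_f == 0:
        return 0.0
    f_eq = nernst_fraction(potential, electro.couple, st.temperature)
    headroom = f_eq - st.frac_ox if target_charge < 0 else st.frac_ox - f_eq
    if headroom <= 0 or delta_f >= headroom:
        raise ValueError(
            f"charge {target_charge} C unreachable: pool headroom is "
            f"{headroom * nfvc:.4g} C at {potential} V")
    return -math.log(1.0 - delta_f / headroom) / electro.k_e


def potential_for_charge(
    target_charge: float,
    electro: ElectroConfig | None = None,
    duration: float = 900.0,
) -> float:
    """Constant potential that delivers a target oxidation charge in a fixed
    application time (the device's varied-potential protocol, 15 min by
    default).  Assumes no cell-mediated re-reduction."""
    electro = electro or ElectroConfig()
    if target_charge > 0:
        raise ValueError("expected an oxidation (negative) charge")
    st = electro.state
    nfvc = electro.couple.n * F_CONST * st.total_moles
    delta_f = abs(target_charge) / nfvc
    relax = 1.0 - math.exp(-electro.k_e * duration)
    f_eq = st.frac_ox + delta_f / relax
    if f_eq >= 1.0:
        raise ValueError(
            f"charge {target_charge} C unreachable in {duration} s: "
            f"would require equilibrium oxidized fraction {f_eq:.3f} >= 1")
    return nernst_potential(f_eq, electro.couple, st.temperature)


@dataclass
class ChargeSynthesisResult:
    """Charge vs integrated-synthesis sweep and its least-squares summary."""

    charges: np.ndarray          # achieved charges, C (negative = oxidation)
    synthesis: np.ndarray        # integrated synthesis at the horizon, au
    slope: float
    intercept: float
    r_squared: float


def charge_synthesis_relation(
    charges: list[float],
    params: CircuitParams | None = None,
    electro: ElectroConfig | None = None,
    horizon: float = 4 * 3600.0,
    mode: str = "duration",
    application_time: float = 900.0,
) -> ChargeSynthesisResult:
    """Integrated reporter synthesis at a fixed horizon as a function of the
    delivered charge.

    ``mode='duration'`` applies the oxidizing potential (+0.5 V) for whatever
    duration delivers each charge; ``mode='potential'`` applies a varied
    potential for a fixed 15-min window.  Equal charges should give equal
    synthesis regardless of mode — the device's charge (not voltage or
    duration) is the controlling variable.  Returns the per-charge synthesis
    and an ordinary least-squares line (slope per |C|).
    """
    params = params or CircuitParams()
    electro = electro or ElectroConfig()
    if len(set(float(c) for c in charges)) < 3:
        raise ValueError("need at least 3 distinct charges")

    achieved = []
    synth = []
    for q in charges:
        if q == 0:
            schedule = SignalSchedule([(None, horizon)])
        elif mode == "duration":
            dur = duration_for_charge(q, electro)
            rest = horizon - dur
            segs: list[tuple[float | None, float]] = [(ON_POTENTIAL, dur)]
            if rest > 0:
                segs.append((None, rest))
            schedule = SignalSchedule(segs)
        elif mode == "potential":
            E = potential_for_charge(q, electro, duration=application_time)
            segs = [(E, application_time)]
            if horizon > application_time:
                segs.append((None, horizon - application_time))
            schedule = SignalSchedule(segs)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        res = simulate_expression(schedule, params, electro)
        achieved.append(res.total_charge)
        synth.append(float(res.true_synthesis[-1]))

    achieved_arr = np.array(achieved)
    synth_arr = np.array(synth)
    fit = stats.linregress(np.abs(achieved_arr), synth_arr)
    return ChargeSynthesisResult(
        charges=achieved_arr, synthesis=synth_arr,
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2))


def cycle_experiment(
    cycle_times: list[float],
    params: CircuitParams | None = None,
    electro: ElectroConfig | None = None,
    P0: float = 0.0,
) -> list[CycleResult]:
    """Single ON/OFF cycle per cycle time: oxidizing potential from t=0 to
    the half cycle, reducing potential to the end.  Records fluorescence at
    the half-cycle and end-of-cycle sample points."""
    params = params or CircuitParams()
    electro = electro or ElectroConfig()
    out = []
    for ct in cycle_times:
        if ct <= 0:
            raise ValueError("cycle times must be positive")
        half = ct / 2.0
        schedule = SignalSchedule([(ON_POTENTIAL, half), (OFF_POTENTIAL, half)])
        res = simulate_expression(schedule, params, electro, P0=P0)
        P = res.trace.fluorescence
        t = res.trace.times
        half_f = float(np.interp(half, t, P))
        out.append(CycleResult(cycle_time=float(ct),
                               half_cycle_fluor=half_f,
                               end_cycle_fluor=float(P[-1])))
    return out


@dataclass(frozen=True)
class DegradationFit:
    k_deg: float
    stderr: float
    n_points: int


def fit_degradation_rate(trace: ExpressionTrace, off_start: float) -> DegradationFit:
    """Estimate the first-order degradation rate from the post-'OFF' decay.

    Log-linear least squares on samples at ``t >= off_start``; returns the
    rate (= minus the slope of log fluorescence) and its standard error.
    """
    mask = trace.times >= off_start
    t = trace.times[mask]
    P = trace.fluorescence[mask]
    if t.size < 4:
        raise ValueError("need at least 4 samples after off_start")
    if np.any(P <= 0):
        raise ValueError("nonpositive fluorescence in the fit window")
    fit = stats.linregress(t, np.log(P))
    stderr = float(fit.stderr)
    if not math.isfinite(stderr):
        # perfect (zero-residual) fits make linregress emit NaN
        resid = np.log(P) - (fit.intercept + fit.slope * t)
        if np.allclose(resid, 0.0):
            stderr = 0.0
    return DegradationFit(k_deg=float(-fit.slope), stderr=stderr,
                          n_points=int(t.size))
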