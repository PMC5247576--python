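"""Bulk-electrolysis model of the ferri/ferrocyanide mediator pool.

The electrogenetic device actuates gene expression by interconverting a
dissolved redox mediator — the hexacyanoferrate couple Fcn(O)/Fcn(R) — at a
working electrode held at a fixed potential.  This module maps an applied
potential program to the oxidized fraction of the mediator pool, the emitted
current, and the integrated charge (coulombs), which is the device's control
variable.

Model
-----
The pool is well stirred and lumped: the oxidized fraction ``f`` relaxes
first-order toward the Nernst equilibrium set by the applied potential,

    df/dt = k_e * (f_eq(E) - f) - k_cell * OD * f

where ``k_e`` is a lumped electrode rate constant and the second term is a
mass-action sink for mediator re-reduction by respiring cells.  The emitted
current is the electrode term only (cells draw no current through the
potentiostat):

    I(t) = -n * F * V * C_tot * k_e * (f_eq - f)

Sign convention: oxidation of the pool produces *negative* current and
charge (the device's 'ON' signals run from 0 down to about -2 C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Faraday constant, C/mol
F_CONST = 96485.332
#: Molar gas constant, J/(mol K)
R_CONST = 8.314462618


@dataclass(frozen=True)
class RedoxCouple:
    """A one- or multi-electron redox couple.

    Parameters
    ----------
    name : str
        Human-readable label.
    E0 : float
        Standard potential in volts vs Ag/AgCl.
    n : int
        Electrons transferred per molecule (``n >= 1``).
    """

    name: str
    E0: float
    n: int = 1

    def __post_init__(self) -> None:
        if not math.isfinite(self.E0):
            raise ValueError("E0 must be finite")
        if self.n < 1:
            raise ValueError("n must be >= 1")


#: The ferricyanide/ferrocyanide couple (E0 ~ +0.2 V vs Ag/AgCl, one electron).
FERRICYANIDE = RedoxCouple(name="Fcn(O/R)", E0=0.2, n=1)


@dataclass
class ElectrolysisState:
    """State of the stirred mediator pool in the working chamber.

    volume in litres, total_conc in mol/L (oxidized + reduced), frac_ox the
    dimensionless oxidized fraction, temperature in kelvin.  Defaults match
    the experimental chamber: 3 ml of 5 mM mediator at 37 C.
    """

    volume: float = 3e-3
    total_conc: float = 5e-3
    frac_ox: float = 0.0
    temperature: float = 310.15

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if self.total_conc <= 0:
            raise ValueError("total_conc must be positive")
        if not 0.0 <= self.frac_ox <= 1.0:
            raise ValueError("frac_ox must lie in [0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    @property
    def total_moles(self) -> float:
        return self.volume * self.total_conc


@dataclass
class SignalSchedule:
    """Piecewise-constant applied-potential program.

    ``segments`` is an ordered list of ``(potential_V, duration_s)`` pairs,
    contiguous in time from t = 0.  A potential of ``None`` denotes open
    circuit (electrode disconnected; no electrode-driven conversion).
    The conventional signals are +0.5 V ('ON', oxidizing) and -0.3 V
    ('OFF', reducing).
    """

    segments: list[tuple[float | None, float]]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule must contain at least one segment")
        for i, (E, dur) in enumerate(self.segments):
            if E is not None and not math.isfinite(E):
                raise ValueError(f"segment {i}: potential must be finite or None")
            if not (math.isfinite(dur) and dur > 0):
                raise ValueError(f"segment {i}: duration must be positive")

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.segments))


@dataclass
class CurrentTrace:
    """Sampled current I(t): times in seconds (strictly increasing), currents
    in amperes. Oxidation current is negative."""

    times: np.ndarray
    currents: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.times.shape != self.currents.shape or self.times.ndim != 1:
            raise ValueError("times and currents must be 1-D arrays of equal length")
        if self.times.size and self.times[0] < 0:
            raise ValueError("times must start at t >= 0")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


def nernst_fraction(E_applied: float, couple: RedoxCouple = FERRICYANIDE,
                    temperature: float = 310.15) -> float:
    """Equilibrium oxidized fraction of a couple at an applied potential.

    Solves the Nernst equation ``E = E0 + (RT/nF) ln([O]/[R])`` for the
    oxidized fraction, giving the logistic

        f = 1 / (1 + exp(-n F (E - E0) / (R T)))

    Monotone nondecreasing in ``E_applied``; equals 0.5 at ``E0``.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if not math.isfinite(E_applied):
        raise ValueError("E_applied must be finite")
    x = couple.n * F_CONST * (E_applied - couple.E0) / (R_CONST * temperature)
    # logistic, numerically safe for large |x|
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    ex = math.exp(x)
    return ex / (1.0 + ex)


def nernst_potential(frac_ox: float, couple: RedoxCouple = FERRICYANIDE,
                     temperature: float = 310.15) -> float:
    """Inverse of :func:`nernst_fraction`: potential at which ``frac_ox`` is
    the equilibrium oxidized fraction. Requires ``0 < frac_ox < 1``."""
    if not 0.0 < frac_ox < 1.0:
        raise ValueError("frac_ox must lie strictly inside (0, 1)")
    vt = R_CONST * temperature / (couple.n * F_CONST)
    return couple.E0 + vt * math.log(frac_ox / (1.0 - frac_ox))


def faraday_charge(delta_moles: float, n: int = 1, oxidation: bool = True) -> float:
    """Charge required to convert ``delta_moles`` of an n-electron couple.

    ``|Q| = n * F * delta_moles``; by the trace sign convention, oxidation
    carries negative sign.  ``delta_moles`` must be nonnegative.
    """
    if delta_moles < 0:
        raise ValueError("delta_moles must be nonnegative")
    if n < 1:
        raise ValueError("n must be >= 1")
    q = n * F_CONST * delta_moles
    return -q if oxidation else q


def integrate_charge(trace: CurrentTrace) -> np.ndarray:
    """Cumulative charge Q(t) = integral of I dt (trapezoid rule).

    Returns an array of the same length as the trace; first element is 0 and
    the final element is the total charge.
    """
    if trace.times.size < 2:
        raise ValueError("need at least 2 samples to integrate")
    from scipy.integrate import cumulative_trapezoid

    return cumulative_trapezoid(trace.currents, trace.times, initial=0.0)


@dataclass
class ElectrolysisResult:
    """Output of :func:`simulate_bulk_electrolysis`."""

    times: np.ndarray
    frac_ox: np.ndarray
    trace: CurrentTrace

    @property
    def total_charge(self) -> float:
        return float(integrate_charge(self.trace)[-1])


def _segment_grid(duration: float, dt: float) -> tuple[int, float]:
    """Number of RK4 steps and uniform step size covering ``duration``."""
    n = max(1, math.ceil(duration / dt - 1e-12))
    return n, duration / n


def simulate_bulk_electrolysis(
    state: ElectrolysisState,
    schedule: SignalSchedule,
    couple: RedoxCouple = FERRICYANIDE,
    k_e: float = math.log(100.0) / 900.0,
    k_cell: float = 0.0,
    cell_density: float = 0.0,
    dt: float = 1.0,
) -> ElectrolysisResult:
    """Integrate the lumped electrolysis model over a potential schedule.

    Within each segment the oxidized fraction obeys

        df/dt = k_e (f_eq - f) - k_cell * cell_density * f

    (the electrode term vanishes in open-circuit segments).  Fixed-step RK4
    at step ``dt`` (the last step of a segment is shortened to land exactly
    on the boundary).  The default ``k_e = ln(100)/900 s^-1`` makes a full
    interconversion 99% complete in 15 min, matching the device's observed
    bulk conversion time.

    Returns times, frac_ox samples and the emitted :class:`CurrentTrace`.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if k_e < 0 or k_cell < 0 or cell_density < 0:
        raise ValueError("rates and cell density must be nonnegative")
    min_dur = min(d for _, d in schedule.segments)
    if dt > min_dur:
        raise ValueError(
            f"dt={dt} exceeds the shortest segment duration {min_dur}")

    nfvc = couple.n * F_CONST * state.total_moles
    sink = k_cell * cell_density

    times = [0.0]
    fracs = [state.frac_ox]
    currents = []

    def current(f: float, f_eq: float | None) -> float:
        if f_eq is None:
            return 0.0
        return -nfvc * k_e * (f_eq - f)

    t = 0.0
    f = state.frac_ox
    # current at t=0 uses the first segment's target
    first_E = schedule.segments[0][0]
    f_eq0 = None if first_E is None else nernst_fraction(first_E, couple, state.temperature)
    currents.append(current(f, f_eq0))

    for seg_idx, (E, dur) in enumerate(schedule.segments):
        f_eq = None if E is None else nernst_fraction(E, couple, state.temperature)
        a = 0.0 if f_eq is None else k_e * f_eq
        b = (0.0 if f_eq is None else k_e) + sink

        def deriv(y: float) -> float:
            return a - b * y

        if seg_idx > 0:
            # The current jumps discontinuously at a potential step.  Record
            # the post-step value a microsecond in so the trapezoid rule sees
            # the jump instead of averaging across it.
            eps = 1e-6
            times.append(t + eps)
            fracs.append(f)
            currents.append(current(f, f_eq))
            t += eps
            dur -= eps

        nsteps, h = _segment_grid(dur, dt)
        for _ in range(nsteps):
            k1 = deriv(f)
            k2 = deriv(f + 0.5 * h * k1)
            k3 = deriv(f + 0.5 * h * k2)
            k4 = deriv(f + h * k3)
            f = f + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
            times.append(t)
            fracs.append(f)
            currents.append(current(f, f_eq))

    times_arr = np.array(times)
    trace = CurrentTrace(times=times_arr, currents=np.array(currents))
    return ElectrolysisResult(times=times_arr, frac_ox=np.array(fracs), trace=trace)
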