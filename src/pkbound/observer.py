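"""Positive interval (state-bounding) observers for uncertain compartmental models.

Two auxiliary systems driven by the measured output y(t) of the unknown plant,

    dxU/dt = (A_hi - L c_lo^T) xU + L y
    dxL/dt = (A_lo - L c_hi^T) xL + L y,

bracket the true state for all time provided both observer matrices are
Metzler (so the error dynamics preserve the sign of the initial bracketing)
and Hurwitz (so the bounds do not blow up), and L >= 0.  The gain L = 0
reduces the observers to open-loop envelope prediction; a linear program can
synthesize the largest admissible measurement feedback.

Propagation is exact for LTI blocks: the driven observers are discretized by a
Van Loan augmented matrix exponential treating y as piecewise linear on the
grid, and :func:`run_observers_with_model` propagates plant and observers as
one coupled LTI system (the configuration in which the observers are wired to
the model output), which is exact to round-off and is what containment
verification uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy.linalg import expm
from scipy.optimize import linprog

from .models import IntervalModel, LinearCompartmentalModel, validate
from .simulate import DEFAULT_HORIZON, DEFAULT_STEP, EnvelopePair, Trajectory, _grid
from .synthetic import SampleSeries

__all__ = [
    "ObserverGain",
    "MeasuredSignal",
    "certify_gain",
    "synthesize_gain",
    "run_observers",
    "observe_from_samples",
    "run_observers_with_model",
]

#: tolerance below which an off-diagonal entry still counts as nonnegative
_METZLER_TOL = 1e-9


@dataclass(frozen=True)
class ObserverGain:
    """Nonnegative observer gain with its positivity/stability certificates.

    ``min_offdiag_*`` is the smallest off-diagonal entry (>= 0 certifies the
    Metzler property) and ``abscissa_*`` the spectral abscissa (< 0 certifies
    stability) of the upper/lower observer matrices.
    """

    L: np.ndarray
    certified: bool
    min_offdiag_upper: float
    min_offdiag_lower: float
    abscissa_upper: float
    abscissa_lower: float
    strategy: str = ""

    def __post_init__(self):
        object.__setattr__(self, "L", np.asarray(self.L, dtype=float))


def _observer_matrices(interval: IntervalModel, L: np.ndarray):
    M_upper = interval.A_hi - np.outer(L, interval.c_lo)
    M_lower = interval.A_lo - np.outer(L, interval.c_hi)
    return M_upper, M_lower


def _min_offdiag(M: np.ndarray) -> float:
    mask = ~np.eye(M.shape[0], dtype=bool)
    return float(M[mask].min())


def certify_gain(interval: IntervalModel, L, strategy: str = "") -> ObserverGain:
    """Independently certify a candidate gain: sign, Metzler and eigenvalue checks."""
    L = np.asarray(L, dtype=float)
    M_up, M_lo = _observer_matrices(interval, L)
    off_up, off_lo = _min_offdiag(M_up), _min_offdiag(M_lo)
    absc_up = float(np.max(np.real(np.linalg.eigvals(M_up))))
    absc_lo = float(np.max(np.real(np.linalg.eigvals(M_lo))))
    certified = (
        bool(np.all(L >= 0))
        and off_up >= -_METZLER_TOL
        and off_lo >= -_METZLER_TOL
        and absc_up < 0
        and absc_lo < 0
    )
    return ObserverGain(
        L=L,
        certified=certified,
        min_offdiag_upper=off_up,
        min_offdiag_lower=off_lo,
        abscissa_upper=absc_up,
        abscissa_lower=absc_lo,
        strategy=strategy,
    )


def synthesize_gain(
    interval: IntervalModel,
    strategy: Literal["zero", "max_feedback"] = "zero",
    l_max: float = 10.0,
    margin: float = 1e-6,
) -> ObserverGain:
    """Synthesize a certified nonnegative observer gain.

    ``zero`` returns L = 0 (open-loop envelope prediction), certified whenever
    both bound matrices are Metzler and Hurwitz — always the case for the
    triangular cascades, whose eigenvalues are their negative diagonals.

    ``max_feedback`` maximizes sum(L) over 0 <= L <= l_max subject to the
    linear Metzler constraints on both observer matrices and a row-sum
    (diagonal-dominance) stability margin ``M 1 <= -margin``; the row-sum bound
    is a linear surrogate for the Hurwitz condition, so if it is infeasible the
    LP is re-solved with the Metzler constraints only and stability is checked
    a posteriori on the eigenvalues.  The box bound ``l_max`` (1/h per unit of
    output) makes the LP well posed: along the observed column the objective is
    otherwise unbounded.

    Raises
    ------
    ValueError
        If no certified gain exists under the given strategy.
    """
    bad = validate(interval)
    if bad:
        raise ValueError("invalid interval model: " + "; ".join(bad))
    if strategy == "zero":
        gain = certify_gain(interval, np.zeros(interval.n), strategy="zero")
        if not gain.certified:
            raise ValueError(
                "L = 0 is not certified: a bound matrix is not Metzler-Hurwitz "
                f"(abscissas {gain.abscissa_upper:.3g}, {gain.abscissa_lower:.3g})"
            )
        return gain
    if strategy != "max_feedback":
        raise ValueError(f"unknown strategy {strategy!r}")

    n = interval.n
    A_ub, b_ub = [], []
    # Metzler: off-diagonal (i,j) of A_hi - L c_lo^T and A_lo - L c_hi^T stays >= 0
    for A_bound, c_vec in ((interval.A_hi, interval.c_lo), (interval.A_lo, interval.c_hi)):
        for i in range(n):
            for j in range(n):
                if i == j or c_vec[j] == 0:
                    continue
                row = np.zeros(n)
                row[i] = c_vec[j]
                A_ub.append(row)
                b_ub.append(A_bound[i, j])
    metzler_rows = len(A_ub)
    # row-sum stability margin: (A_bound - L c^T) 1 <= -margin
    for A_bound, c_vec in ((interval.A_hi, interval.c_lo), (interval.A_lo, interval.c_hi)):
        csum = c_vec.sum()
        for i in range(n):
            row = np.zeros(n)
            row[i] = -csum
            A_ub.append(row)
            b_ub.append(-margin - A_bound[i].sum())
    objective = -np.ones(n)  # maximize sum(L)
    res = linprog(
        objective,
        A_ub=np.array(A_ub),
        b_ub=np.array(b_ub),
        bounds=[(0.0, l_max)] * n,
        method="highs",
    )
    if not res.success:
        res = linprog(
            objective,
            A_ub=np.array(A_ub[:metzler_rows]),
            b_ub=np.array(b_ub[:metzler_rows]),
            bounds=[(0.0, l_max)] * n,
            method="highs",
        )
    if not res.success:
        raise ValueError(
            "max_feedback synthesis failed: no gain satisfies the Metzler constraints; "
            "use strategy='zero'"
        )
    gain = certify_gain(interval, np.maximum(res.x, 0.0), strategy="max_feedback")
    if not gain.certified:
        raise ValueError(
            "max_feedback synthesis produced an uncertified gain "
            f"(abscissas {gain.abscissa_upper:.3g}, {gain.abscissa_lower:.3g}); "
            "use strategy='zero'"
        )
    return gain


@dataclass(frozen=True)
class MeasuredSignal:
    """A sampled measurement made into a nonnegative function y(t) on the horizon.

    Interpolation is linear (default) or zero-order hold; beyond the last
    sample the last value is held, before the first sample the first value.
    Values are clamped at zero, and the samples are reproduced exactly.
    """

    series: SampleSeries
    interp: Literal["linear", "zoh"] = "linear"

    def __post_init__(self):
        if self.interp not in ("linear", "zoh"):
            raise ValueError(f"interp must be 'linear' or 'zoh', got {self.interp!r}")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        ts, vs = self.series.times, self.series.values
        if self.interp == "linear":
            out = np.interp(t, ts, vs)
        else:
            idx = np.clip(np.searchsorted(ts, t, side="right") - 1, 0, len(ts) - 1)
            out = vs[idx]
        return np.maximum(out, 0.0)


def _vanloan_blocks(M: np.ndarray, h: float):
    """E = e^{Mh}, F1 = int_0^h e^{Ms} ds, F2 = int_0^h e^{M(h-s)} s ds via one augmented expm."""
    n = M.shape[0]
    C = np.zeros((3 * n, 3 * n))
    C[:n, :n] = M
    C[:n, n : 2 * n] = np.eye(n)
    C[n : 2 * n, 2 * n :] = np.eye(n)
    E = expm(C * h)
    return E[:n, :n], E[:n, n : 2 * n], E[:n, 2 * n :]


def _drive_observer(M: np.ndarray, x0: np.ndarray, L: np.ndarray, y_grid: np.ndarray, h: float):
    """Exact propagation of dx/dt = M x + L y(t) with y piecewise linear on the grid."""
    E, F1, F2 = _vanloan_blocks(M, h)
    slopes = np.diff(y_grid) / h
    states = np.empty((y_grid.size, M.shape[0]))
    states[0] = x0
    for k in range(y_grid.size - 1):
        states[k + 1] = E @ states[k] + F1 @ (L * y_grid[k]) + F2 @ (L * slopes[k])
    return states


def run_observers(
    interval: IntervalModel,
    gain: ObserverGain,
    y: MeasuredSignal | Callable[[np.ndarray], np.ndarray],
    x0_bounds: tuple[np.ndarray, np.ndarray] | None = None,
    horizon: float = DEFAULT_HORIZON,
    step: float = DEFAULT_STEP,
) -> EnvelopePair:
    """Run the twin state-bounding observers driven by the measured output y.

    The returned pair bounds every state of every system inside the interval
    whose true initial state lies within ``x0_bounds`` (default: the interval's
    own x0 bounds) and whose exact output is y.  Refuses to run with an
    uncertified gain, since the guarantee would be void.
    """
    if not gain.certified:
        raise ValueError("refusing to run observers with an uncertified gain")
    bad = validate(interval)
    if bad:
        raise ValueError("invalid interval model: " + "; ".join(bad))
    if x0_bounds is None:
        x0_lo, x0_hi = interval.x0_lo, interval.x0_hi
    else:
        x0_lo = np.asarray(x0_bounds[0], dtype=float)
        x0_hi = np.asarray(x0_bounds[1], dtype=float)
        if np.any(x0_lo > x0_hi):
            raise ValueError("x0 lower bound exceeds upper bound")
    times = _grid(horizon, step)
    y_grid = np.asarray(y(times), dtype=float)
    if y_grid.shape != times.shape:
        raise ValueError("measured signal must evaluate elementwise on the time grid")
    if np.any(y_grid < 0):
        raise ValueError("measured signal must be nonnegative")
    M_up, M_lo = _observer_matrices(interval, gain.L)
    labels = interval.nominal.labels
    upper_states = _drive_observer(M_up, x0_hi, gain.L, y_grid, step)
    lower_states = _drive_observer(M_lo, x0_lo, gain.L, y_grid, step)
    upper = Trajectory(times, upper_states, upper_states @ interval.c_hi, labels)
    lower = Trajectory(times, lower_states, lower_states @ interval.c_lo, labels)
    return EnvelopePair(lower=lower, upper=upper)


def observe_from_samples(
    interval: IntervalModel,
    gain: ObserverGain,
    samples: SampleSeries,
    interp: Literal["linear", "zoh"] = "linear",
    x0_bounds: tuple[np.ndarray, np.ndarray] | None = None,
    horizon: float = DEFAULT_HORIZON,
    step: float = DEFAULT_STEP,
) -> EnvelopePair:
    """Bound all compartment amounts from a measured sample series of the observed compartment.

    The samples (which must be in amount units, mg) are interpolated into a
    continuous nonnegative signal and fed to :func:`run_observers`.
    """
    if samples.unit != "mg":
        raise ValueError(
            "observer input must be amounts in mg; convert concentrations first "
            "(identify.concentrations_to_amounts)"
        )
    signal = MeasuredSignal(series=samples, interp=interp)
    return run_observers(interval, gain, signal, x0_bounds, horizon, step)


def run_observers_with_model(
    interval: IntervalModel,
    gain: ObserverGain,
    model: LinearCompartmentalModel,
    horizon: float = DEFAULT_HORIZON,
    step: float = DEFAULT_STEP,
) -> tuple[EnvelopePair, Trajectory]:
    """Wire the observers to the output of a simulated plant and propagate the coupled system.

    Plant and both observers form one LTI system, propagated exactly per step,
    so the bracketing guarantee can be verified to round-off precision.
    Returns the bound pair and the plant trajectory.
    """
    if not gain.certified:
        raise ValueError("refusing to run observers with an uncertified gain")
    bad = validate(model)
    if bad:
        raise ValueError("invalid plant model: " + "; ".join(bad))
    n = interval.n
    if model.n != n:
        raise ValueError("plant and interval model dimensions differ")
    M_up, M_lo = _observer_matrices(interval, gain.L)
    Lc = np.outer(gain.L, model.c)
    Z = np.zeros((3 * n, 3 * n))
    Z[:n, :n] = model.A
    Z[n : 2 * n, :n] = Lc
    Z[n : 2 * n, n : 2 * n] = M_up
    Z[2 * n :, :n] = Lc
    Z[2 * n :, 2 * n :] = M_lo
    times = _grid(horizon, step)
    P = expm(Z * step)
    z = np.empty((times.size, 3 * n))
    z[0] = np.concatenate([model.x0, interval.x0_hi, interval.x0_lo])
    for k in range(1, times.size):
        z[k] = P @ z[k - 1]
    labels = interval.nominal.labels
    plant = Trajectory(times, z[:, :n], z[:, :n] @ model.c, labels)
    upper = Trajectory(times, z[:, n : 2 * n], z[:, n : 2 * n] @ interval.c_hi, labels)
    lower = Trajectory(times, z[:, 2 * n :], z[:, 2 * n :] @ interval.c_lo, labels)
    return EnvelopePair(lower=lower, upper=upper), plant
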