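"""Rate-constant identification from sampled measurements.

Fits the rate constants of a chosen compartmental structure by multi-start
nonlinear least squares on amounts (the problem is small — a handful of
samples against 3-4 parameters — but poorly conditioned, so a single local
fit is indefensible; starts are drawn log-uniformly and the best is kept).

A structural caveat dictates how results are reported: observing a triangular
cascade from its terminal compartment determines the set of exponential rates
and the product ka*k23 (for the three-compartment chain), but *not* which rate
plays which role — several parameter vectors produce bit-identical outputs
(the oral two-compartment model has the classic "flip-flop" twin).  fit_rates
therefore clusters all sum-of-squares-tied optima, reports every equivalent
mode, and returns a canonical representative: the lexicographically smallest
parameter tuple in declared order (absorption rate first).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import least_squares

from .models import LinearCompartmentalModel
from .simulate import closed_form_cascade
from .synthetic import SampleSeries

__all__ = ["FitResult", "concentrations_to_amounts", "fit_rates"]

_STRUCTURES = {
    "two_compartment": {"params": ("ka", "ke1", "ke2"), "n": 2, "default_observed": 2},
    "three_compartment": {"params": ("ka", "ke1", "k23", "ke3"), "n": 3, "default_observed": 3},
}


def concentrations_to_amounts(series: SampleSeries, blood_volume_ml: float) -> SampleSeries:
    """Convert a concentration series (mg/mL) to amounts (mg): amount = concentration x volume."""
    if series.unit != "mg_per_ml":
        raise ValueError(f"series unit is {series.unit!r}; conversion expects 'mg_per_ml'")
    if blood_volume_ml is None or not blood_volume_ml > 0:
        raise ValueError(
            "a positive blood volume is required to convert concentrations to amounts; "
            "set the blood_volume_ml configuration key"
        )
    return SampleSeries(
        times=series.times,
        values=series.values * blood_volume_ml,
        unit="mg",
        label=series.label,
    )


@dataclass(frozen=True)
class FitResult:
    """Outcome of a multi-start rate-constant fit.

    ``params`` is the canonical representative (see module docstring);
    ``equivalent_modes`` lists every distinct parameter vector whose objective
    ties the optimum, canonical one included.  ``trace`` holds one record per
    start for reproducibility and dispersion diagnostics.
    """

    params: dict[str, float]
    sse: float
    n_starts: int
    converged: bool
    degenerate: bool = False
    equivalent_modes: tuple[dict[str, float], ...] = ()
    trace: tuple[dict, ...] = ()

    def dispersion(self) -> dict[str, float]:
        """Across converged starts, max/min ratio per parameter — a cheap conditioning probe."""
        out = {}
        finals = [t["params"] for t in self.trace if t["success"]]
        for name in self.params:
            vals = np.array([f[name] for f in finals])
            vals = vals[vals > 0]
            out[name] = float(vals.max() / vals.min()) if vals.size else np.inf
        return out


def _build_A(structure: str, theta: np.ndarray) -> np.ndarray:
    if structure == "two_compartment":
        ka, ke1, ke2 = theta
        return np.array([[-(ka + ke1), 0.0], [ka, -ke2]])
    ka, ke1, k23, ke3 = theta
    return np.array([[-(ka + ke1), 0.0, 0.0], [ka, -k23, 0.0], [0.0, k23, -ke3]])


def _output_at(structure: str, theta: np.ndarray, dose: float, observed: int, times: np.ndarray):
    A = _build_A(structure, theta)
    n = A.shape[0]
    x0 = np.zeros(n)
    x0[0] = dose
    lam = np.diag(A)
    gaps = np.abs(np.subtract.outer(lam, lam))[~np.eye(n, dtype=bool)]
    model = LinearCompartmentalModel(A=A, b=np.zeros(n), c=np.zeros(n), x0=x0)
    if gaps.min() > 1e-9 * max(1.0, np.abs(lam).max()):
        states = closed_form_cascade(model, times)
    else:  # (near-)confluent rates: fall back to the matrix exponential
        states = np.array([expm(A * t) @ x0 for t in times])
    return states[:, observed - 1]


def _canonical_sort_key(params: dict[str, float], order: tuple[str, ...]):
    # round to 6 significant digits so float jitter cannot flip the ordering
    return tuple(float(f"{params[k]:.6g}") for k in order)


def fit_rates(
    structure: str,
    samples: SampleSeries,
    dose: float,
    observed: int | None = None,
    starts: int = 32,
    seed: int = 0,
    log_residuals: bool = False,
) -> FitResult:
    """Estimate the rate constants of ``structure`` from an amount sample series.

    Minimizes sum_i (y_model(t_i) - y_i)^2 over nonnegative rate constants,
    from ``starts`` log-uniform starting points in [1e-3, 10] 1/h (seeded).
    ``log_residuals`` switches to residuals on log(1 + y), weighting relative
    rather than absolute error.

    Parameters
    ----------
    structure : {"two_compartment", "three_compartment"}
    samples : SampleSeries in mg (convert concentrations first).
    dose : administered dose in mg, encoded as x1(0).
    observed : 1-based measured compartment; defaults to the structure's
        terminal sampling site (2 resp. 3).
    """
    if structure not in _STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}; use one of {sorted(_STRUCTURES)}")
    if samples.unit != "mg":
        raise ValueError("fit_rates expects amounts in mg; convert concentrations first")
    info = _STRUCTURES[structure]
    names = info["params"]
    observed = info["default_observed"] if observed is None else int(observed)
    if not 1 <= observed <= info["n"]:
        raise ValueError(f"observed compartment must be in 1..{info['n']}, got {observed}")
    if len(samples) < len(names):
        raise ValueError(
            f"need at least {len(names)} samples to fit {len(names)} rate constants, "
            f"got {len(samples)}"
        )
    times, values = samples.times, samples.values

    def residuals(theta):
        y = _output_at(structure, theta, dose, observed, times)
        if log_residuals:
            return np.log1p(np.maximum(y, 0.0)) - np.log1p(values)
        return y - values

    rng = np.random.default_rng(seed)
    start_points = 10.0 ** rng.uniform(-3.0, 1.0, size=(starts, len(names)))
    trace = []
    for x_start in start_points:
        try:
            res = least_squares(
                residuals,
                x_start,
                bounds=(0.0, np.inf),
                ftol=1e-15,
                xtol=1e-15,
                gtol=1e-15,
                max_nfev=4000,
            )
            sse = float(2 * res.cost)
            trace.append(
                {
                    "start": dict(zip(names, x_start)),
                    "params": dict(zip(names, res.x)),
                    "sse": sse,
                    "success": bool(res.success),
                }
            )
        except Exception as exc:  # pragma: no cover - optimizer pathologies
            trace.append(
                {"start": dict(zip(names, x_start)), "params": None, "sse": np.inf,
                 "success": False, "error": str(exc)}
            )
    converged = [t for t in trace if t["success"] and np.isfinite(t["sse"])]
    if not converged:
        raise RuntimeError(
            "no start converged; per-start diagnostics: "
            + "; ".join(str(t.get("error", "failed")) for t in trace)
        )
    best_sse = min(t["sse"] for t in converged)
    tol = best_sse * 1e-6 + 1e-14
    tied = [t for t in converged if t["sse"] <= best_sse + tol]
    # cluster SSE-tied optima into distinct modes (relative parameter distance)
    modes: list[dict[str, float]] = []
    for t in tied:
        vec = np.array([t["params"][k] for k in names])
        for m in modes:
            mvec = np.array([m[k] for k in names])
            if np.all(np.abs(vec - mvec) <= 1e-3 * np.maximum(np.abs(mvec), 1e-9)):
                break
        else:
            modes.append(dict(t["params"]))
    modes.sort(key=lambda p: _canonical_sort_key(p, names))
    canonical = modes[0]
    degenerate = bool(np.max(values) == 0)
    return FitResult(
        params=canonical,
        sse=best_sse,
        n_starts=starts,
        converged=True,
        degenerate=degenerate,
        equivalent_modes=tuple(modes),
        trace=tuple(trace),
    )
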