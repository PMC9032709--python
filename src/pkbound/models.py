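"""Linear compartmental pharmacokinetic models and their interval (uncertain) forms.

A compartmental model here is the positive LTI system

    dx/dt = A x + b u(t),    y = c^T x,

where ``x`` holds drug amounts (mg) per compartment, ``A`` (1/h) is Metzler
(off-diagonal entries >= 0) with non-positive diagonal, and an oral bolus dose
enters as the initial amount of the first (GIT) compartment.  Parametric
uncertainty is a fraction ``delta`` applied elementwise, producing an interval
model whose bound matrices are again Metzler, so trajectories of any system
inside the interval are bracketed by the bound systems' trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LinearCompartmentalModel",
    "UncertaintySpec",
    "IntervalModel",
    "build_two_compartment",
    "build_three_compartment",
    "expand_uncertainty",
    "validate",
]

#: tolerance for sign checks on matrix entries
_SIGN_TOL = 1e-12


def _as_1d(v, n: int, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.shape != (n,):
        raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
    return arr


@dataclass(frozen=True)
class LinearCompartmentalModel:
    """Nominal positive LTI compartmental model.

    Parameters
    ----------
    A : (n, n) array
        Rate matrix in 1/h; Metzler with non-positive diagonal for a valid model.
    b : (n,) array
        Dose-routing vector (dimensionless); retained for infusion inputs,
        unused when the dose is encoded in ``x0``.
    c : (n,) array
        Observation vector selecting (or weighting) the measured compartment.
    x0 : (n,) array
        Initial amounts in mg.
    labels : sequence of str
        Compartment names, e.g. ``("GIT", "central")``.
    """

    A: np.ndarray
    b: np.ndarray
    c: np.ndarray
    x0: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        if A.shape[0] != A.shape[1]:
            raise ValueError(f"A must be square, got shape {A.shape}")
        n = A.shape[0]
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "b", _as_1d(self.b, n, "b"))
        object.__setattr__(self, "c", _as_1d(self.c, n, "c"))
        object.__setattr__(self, "x0", _as_1d(self.x0, n, "x0"))
        labels = tuple(self.labels) if self.labels else tuple(f"x{i + 1}" for i in range(n))
        if len(labels) != n:
            raise ValueError(f"need {n} labels, got {len(labels)}")
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def observed_compartment(self) -> int:
        """1-based index of the compartment with the largest weight in c."""
        return int(np.argmax(self.c)) + 1

    def validate(self) -> list[str]:
        return validate(self)

    def is_valid(self) -> bool:
        return not validate(self)


@dataclass(frozen=True)
class UncertaintySpec:
    """Elementwise relative uncertainty: each nonzero entry q maps to q ± delta*|q|.

    ``delta`` applies to the nonzero entries of A and c; ``x0_delta`` to those of
    x0 (the administered dose is known only approximately).  Optional per-entry
    overrides replace the delta-derived bounds wholesale for A and/or c.
    """

    delta: float
    x0_delta: float = 0.0
    A_bounds: tuple[np.ndarray, np.ndarray] | None = None
    c_bounds: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self):
        if not 0.0 <= self.delta < 1.0:
            raise ValueError(f"delta must be in [0, 1), got {self.delta}")
        if not 0.0 <= self.x0_delta < 1.0:
            raise ValueError(f"x0_delta must be in [0, 1), got {self.x0_delta}")


@dataclass(frozen=True)
class IntervalModel:
    """Elementwise bounds [A_lo, A_hi], [c_lo, c_hi], [x0_lo, x0_hi] around a nominal model."""

    A_lo: np.ndarray
    A_hi: np.ndarray
    c_lo: np.ndarray
    c_hi: np.ndarray
    x0_lo: np.ndarray
    x0_hi: np.ndarray
    nominal: LinearCompartmentalModel

    def __post_init__(self):
        n = self.nominal.n
        object.__setattr__(self, "A_lo", np.atleast_2d(np.asarray(self.A_lo, dtype=float)))
        object.__setattr__(self, "A_hi", np.atleast_2d(np.asarray(self.A_hi, dtype=float)))
        for name in ("c_lo", "c_hi", "x0_lo", "x0_hi"):
            object.__setattr__(self, name, _as_1d(getattr(self, name), n, name))

    @property
    def n(self) -> int:
        return self.nominal.n

    def lower_model(self) -> LinearCompartmentalModel:
        """The bound system generating the lower envelope: (A_lo, c_lo, x0_lo)."""
        return LinearCompartmentalModel(
            A=self.A_lo, b=self.nominal.b, c=self.c_lo, x0=self.x0_lo, labels=self.nominal.labels
        )

    def upper_model(self) -> LinearCompartmentalModel:
        """The bound system generating the upper envelope: (A_hi, c_hi, x0_hi)."""
        return LinearCompartmentalModel(
            A=self.A_hi, b=self.nominal.b, c=self.c_hi, x0=self.x0_hi, labels=self.nominal.labels
        )

    def validate(self) -> list[str]:
        return validate(self)

    def is_valid(self) -> bool:
        return not validate(self)


def _metzler_violations(A: np.ndarray, name: str) -> list[str]:
    out = []
    n = A.shape[0]
    for i in range(n):
        for j in range(n):
            if i != j and A[i, j] < -_SIGN_TOL:
                out.append(f"{name}[{i + 1},{j + 1}] = {A[i, j]:.6g} < 0 (not Metzler)")
    return out


def validate(obj: LinearCompartmentalModel | IntervalModel) -> list[str]:
    """Diagnostic check of the structural invariants; returns violations (empty iff valid).

    For a nominal model: Metzler A, non-positive diagonal, nonnegative b, c, x0.
    For an interval model: both bound matrices Metzler, and elementwise ordering
    lo <= nominal <= hi for A, c and x0.
    """
    if isinstance(obj, IntervalModel):
        viol = []
        viol += _metzler_violations(obj.A_lo, "A_lo")
        viol += _metzler_violations(obj.A_hi, "A_hi")
        nom = obj.nominal
        for name, lo, mid, hi in (
            ("A", obj.A_lo, nom.A, obj.A_hi),
            ("c", obj.c_lo, nom.c, obj.c_hi),
            ("x0", obj.x0_lo, nom.x0, obj.x0_hi),
        ):
            bad_lo = np.argwhere(lo > mid + _SIGN_TOL)
            bad_hi = np.argwhere(mid > hi + _SIGN_TOL)
            for idx in bad_lo:
                pos = ",".join(str(i + 1) for i in idx)
                viol.append(f"{name}_lo[{pos}] exceeds nominal (ordering violated)")
            for idx in bad_hi:
                pos = ",".join(str(i + 1) for i in idx)
                viol.append(f"nominal {name}[{pos}] exceeds {name}_hi (ordering violated)")
        viol += validate(nom)
        return viol

    viol = _metzler_violations(obj.A, "A")
    for i in range(obj.n):
        if obj.A[i, i] > _SIGN_TOL:
            viol.append(f"A[{i + 1},{i + 1}] = {obj.A[i, i]:.6g} > 0 (diagonal must be <= 0)")
    for name in ("b", "c", "x0"):
        v = getattr(obj, name)
        for (i,) in np.argwhere(v < -_SIGN_TOL):
            viol.append(f"{name}[{i + 1}] = {v[i]:.6g} < 0")
    return viol


def _require_positive_rates(**rates: float) -> None:
    for name, value in rates.items():
        if not value > 0:
            raise ValueError(f"rate constant {name} must be > 0, got {value}")


def build_two_compartment(
    ka: float, ke1: float, ke2: float, dose: float
) -> LinearCompartmentalModel:
    """Two-compartment oral-absorption model (GIT -> central), observed in the central compartment.

    x1 is the amount in the GIT (absorption rate ka, local elimination ke1),
    x2 the amount in the central (blood) compartment eliminated at ke2.
    The bolus dose (mg) enters as x1(0).

    ::

        A = [[-(ka+ke1),    0 ],
             [    ka,     -ke2]],   c = (0, 1),   x0 = (dose, 0)
    """
    _require_positive_rates(ka=ka, ke1=ke1, ke2=ke2)
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose}")
    A = np.array([[-(ka + ke1), 0.0], [ka, -ke2]])
    return LinearCompartmentalModel(
        A=A,
        b=np.array([1.0, 0.0]),
        c=np.array([0.0, 1.0]),
        x0=np.array([float(dose), 0.0]),
        labels=("GIT", "central"),
    )


def build_three_compartment(
    ka: float, ke1: float, k23: float, ke3: float, dose: float, observed: int = 3
) -> LinearCompartmentalModel:
    """Three-compartment cascade GIT -> central -> tissue.

    x1: GIT (absorption ka, elimination ke1); x2: central, transferring to
    tissue at k23; x3: tissue, eliminated at ke3.  ``observed`` is the 1-based
    compartment whose amount is measured; blood samples are typically drawn
    from the tissue compartment (observed=3, the default).  Observing x1 leaves
    x2, x3 unobservable in this triangular structure, but is constructible.
    """
    _require_positive_rates(ka=ka, ke1=ke1, k23=k23, ke3=ke3)
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose}")
    if observed not in (1, 2, 3):
        raise ValueError(f"observed compartment must be 1, 2 or 3, got {observed}")
    A = np.array(
        [
            [-(ka + ke1), 0.0, 0.0],
            [ka, -k23, 0.0],
            [0.0, k23, -ke3],
        ]
    )
    c = np.zeros(3)
    c[observed - 1] = 1.0
    return LinearCompartmentalModel(
        A=A,
        b=np.array([1.0, 0.0, 0.0]),
        c=c,
        x0=np.array([float(dose), 0.0, 0.0]),
        labels=("GIT", "central", "tissue"),
    )


def expand_uncertainty(
    model: LinearCompartmentalModel, spec: UncertaintySpec
) -> IntervalModel:
    """Expand a nominal model into elementwise interval bounds.

    Every nonzero entry q of A (and of c, and — under ``x0_delta`` — of x0)
    maps to [q - delta*|q|, q + delta*|q|]; structural zeros stay zero in both
    bounds.  The lumped diagonal -(ka+ke1) is perturbed as a single quantity.
    A_hi is the entrywise maximum (diagonals shrunk in magnitude, off-diagonals
    grown), A_lo the entrywise minimum; both inherit the Metzler property for
    delta < 1.
    """
    bad = validate(model)
    if bad:
        raise ValueError("invalid model: " + "; ".join(bad))
    d = spec.delta
    if spec.A_bounds is not None:
        A_lo, A_hi = (np.asarray(m, dtype=float) for m in spec.A_bounds)
    else:
        A_lo = model.A - d * np.abs(model.A)
        A_hi = model.A + d * np.abs(model.A)
    if spec.c_bounds is not None:
        c_lo, c_hi = (np.asarray(v, dtype=float) for v in spec.c_bounds)
    else:
        c_lo = model.c - d * np.abs(model.c)
        c_hi = model.c + d * np.abs(model.c)
    dx = spec.x0_delta
    x0_lo = model.x0 - dx * np.abs(model.x0)
    x0_hi = model.x0 + dx * np.abs(model.x0)
    interval = IntervalModel(
        A_lo=A_lo, A_hi=A_hi, c_lo=c_lo, c_hi=c_hi, x0_lo=x0_lo, x0_hi=x0_hi, nominal=model
    )
    bad = validate(interval)
    if bad:  # unreachable under the ± rule with delta < 1; guards overrides
        raise ValueError("uncertainty expansion produced an invalid interval: " + "; ".join(bad))
    return interval
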