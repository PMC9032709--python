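"""Therapeutic-range assessment of guaranteed envelopes.

A therapy is *guaranteed* in range at time t when the whole uncertainty
envelope of the assessed compartment lies inside [lo, hi]: the lower bound
certifies effectiveness (x_lo >= lo) and the upper bound certifies safety
(x_hi <= hi).  Outside the guaranteed set, some admissible system may be
under- or over-dosed — which bound breaches is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .simulate import EnvelopePair

__all__ = ["TherapeuticRange", "RangeAssessment", "assess_range"]


@dataclass(frozen=True)
class TherapeuticRange:
    """Amount window [lo, hi] (mg) that the 1-based ``compartment`` must stay within."""

    lo: float
    hi: float
    compartment: int

    def __post_init__(self):
        if not (0 <= self.lo < self.hi):
            raise ValueError(f"need 0 <= lo < hi, got lo={self.lo}, hi={self.hi}")


@dataclass(frozen=True)
class RangeAssessment:
    """Guaranteed-in-range time set and its complement.

    ``guaranteed_in_range``: disjoint, sorted (start, end) intervals (h) where
    the entire envelope lies inside the range.  ``possibly_out``: the
    complementary intervals, each with the set of breaches observed inside it
    ("below_lo" — the lower envelope bound dips under lo; "above_hi" — the
    upper bound exceeds hi).  ``time_guaranteed`` is the measure of the
    guaranteed set.
    """

    guaranteed_in_range: tuple[tuple[float, float], ...]
    possibly_out: tuple[tuple[float, float, tuple[str, ...]], ...]
    time_guaranteed: float

    def to_dict(self) -> dict:
        return {
            "guaranteed_in_range": [list(iv) for iv in self.guaranteed_in_range],
            "possibly_out": [
                {"start_h": s, "end_h": e, "breaches": list(b)} for s, e, b in self.possibly_out
            ],
            "time_guaranteed_h": self.time_guaranteed,
        }


def _crossing(t0, t1, g0, g1):
    return t0 + (t1 - t0) * g0 / (g0 - g1)


def assess_range(envelope: EnvelopePair, trange: TherapeuticRange) -> RangeAssessment:
    """Compute the guaranteed-in-range time set by interval arithmetic on the grid.

    The guard function g(t) = min(x_lo(t) - lo, hi - x_hi(t)) is evaluated on
    the grid and its sign changes located by linear interpolation; g >= 0
    defines the guaranteed set.
    """
    if not 1 <= trange.compartment <= envelope.lower.n:
        raise ValueError(
            f"compartment {trange.compartment} not in envelope (n={envelope.lower.n})"
        )
    times = envelope.times
    x_lo = envelope.lower.compartment(trange.compartment)
    x_hi = envelope.upper.compartment(trange.compartment)
    g_eff = x_lo - trange.lo
    g_safe = (trange.hi - x_hi) if math.isfinite(trange.hi) else np.full_like(x_hi, np.inf)
    g = np.minimum(g_eff, g_safe)
    ok = g >= 0

    guaranteed: list[tuple[float, float]] = []
    start = times[0] if ok[0] else None
    for k in range(1, times.size):
        if ok[k] and not ok[k - 1]:
            start = _crossing(times[k - 1], times[k], g[k - 1], g[k]) if np.isfinite(
                g[k - 1]
            ) else times[k]
        elif not ok[k] and ok[k - 1]:
            end = _crossing(times[k - 1], times[k], g[k - 1], g[k]) if np.isfinite(
                g[k]
            ) else times[k - 1]
            guaranteed.append((float(start), float(end)))
            start = None
    if start is not None:
        guaranteed.append((float(start), float(times[-1])))
    guaranteed = [(s, e) for s, e in guaranteed if e > s]

    # complementary intervals with their breach causes
    possibly_out: list[tuple[float, float]] = []
    cursor = float(times[0])
    for s, e in guaranteed:
        if s > cursor:
            possibly_out.append((cursor, s))
        cursor = e
    if cursor < times[-1]:
        possibly_out.append((cursor, float(times[-1])))
    annotated = []
    for s, e in possibly_out:
        inside = (times >= s - 1e-12) & (times <= e + 1e-12)
        breaches = []
        if np.any(g_eff[inside] < 0):
            breaches.append("below_lo")
        if np.any(g_safe[inside] < 0):
            breaches.append("above_hi")
        annotated.append((s, e, tuple(breaches)))

    time_guaranteed = float(sum(e - s for s, e in guaranteed))
    return RangeAssessment(
        guaranteed_in_range=tuple(guaranteed),
        possibly_out=tuple(annotated),
        time_guaranteed=time_guaranteed,
    )
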