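"""Synthetic sample series, random in-interval systems, and the shipped reference datasets.

Everything the other modules need for testing is generated here: noisy sampled
measurements emulating the in vivo design (6-7 samples over 0-6 h after a
50 mg oral dose, assay error proportional to the signal), random systems drawn
from an interval model (the "true animal" a state-bounding observer must
bracket), and the published reference data — sampled amounts/concentrations
and identified rate-constant sets with and without the absorption-modifying
tenside — shipped as plain-text fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal

import numpy as np
from scipy.linalg import expm

from .models import IntervalModel, LinearCompartmentalModel

__all__ = [
    "SampleSeries",
    "NoiseSpec",
    "sample_model",
    "sample_interval_system",
    "fixtures",
    "fixture_metadata",
]

Unit = Literal["mg", "mg_per_ml"]


@dataclass(frozen=True)
class SampleSeries:
    """Discrete timestamped measurements of one observed quantity.

    times are strictly increasing hours; values are nonnegative amounts (mg)
    or concentrations (mg/mL) — the unit tag is mandatory so the two can never
    be mixed silently.
    """

    times: np.ndarray
    values: np.ndarray
    unit: Unit = "mg"
    label: str = ""

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.shape != values.shape or times.ndim != 1:
            raise ValueError(
                f"times and values must be equal-length 1-D arrays, got {times.shape} vs {values.shape}"
            )
        if self.unit not in ("mg", "mg_per_ml"):
            raise ValueError(f"unit must be 'mg' or 'mg_per_ml', got {self.unit!r}")
        for k in range(1, times.size):
            if times[k] <= times[k - 1]:
                raise ValueError(f"sample times must be strictly increasing (row {k + 1})")
        for k in range(times.size):
            if values[k] < 0:
                raise ValueError(f"negative sample value {values[k]} (row {k + 1})")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model.

    ``multiplicative_lognormal`` multiplies each nonzero value by a unit-mean
    lognormal factor with coefficient of variation ``level`` (assay errors in
    PK scale with the signal, and positivity needs no truncation).
    ``additive_gaussian_truncated`` adds zero-mean Gaussian noise with standard
    deviation ``level`` times the series peak, truncated at zero.  Exact zeros
    (e.g. the pre-dose sample) are left at zero by both models.
    """

    model: Literal["multiplicative_lognormal", "additive_gaussian_truncated"] = (
        "multiplicative_lognormal"
    )
    level: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.level < 0:
            raise ValueError(f"noise level must be >= 0, got {self.level}")
        if self.model not in ("multiplicative_lognormal", "additive_gaussian_truncated"):
            raise ValueError(f"unknown noise model {self.model!r}")


def _output_at_times(model: LinearCompartmentalModel, times: np.ndarray) -> np.ndarray:
    return np.array([model.c @ (expm(model.A * t) @ model.x0) for t in times])


def sample_model(
    model: LinearCompartmentalModel, times, noise: NoiseSpec | None = None
) -> SampleSeries:
    """Sample the model's observed output at the given times and apply measurement noise."""
    times = np.asarray(times, dtype=float)
    clean = _output_at_times(model, times)
    clean = np.maximum(clean, 0.0)  # clip integrator-level negatives
    if noise is None or noise.level == 0:
        values = clean
    else:
        rng = np.random.default_rng(noise.seed)
        nonzero = clean > 0
        values = clean.copy()
        if noise.model == "multiplicative_lognormal":
            sigma = np.sqrt(np.log1p(noise.level**2))
            factors = np.exp(sigma * rng.standard_normal(times.size) - 0.5 * sigma**2)
            values[nonzero] *= factors[nonzero]
        else:
            sd = noise.level * clean.max()
            values[nonzero] = np.maximum(
                values[nonzero] + sd * rng.standard_normal(nonzero.sum()), 0.0
            )
    return SampleSeries(times=times, values=values, unit="mg", label=f"simulated:{model.labels}")


def sample_interval_system(
    interval: IntervalModel, seed: int | np.random.Generator = 0
) -> LinearCompartmentalModel:
    """Draw a random system elementwise-uniformly inside the interval bounds.

    Structural zeros (entries zero in both bounds) stay zero, so every draw is
    Metzler by construction and passes validation; this supplies the unknown
    "true" system for Monte-Carlo containment checks.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A = interval.A_lo + (interval.A_hi - interval.A_lo) * rng.uniform(size=interval.A_lo.shape)
    c = interval.c_lo + (interval.c_hi - interval.c_lo) * rng.uniform(size=interval.c_lo.shape)
    x0 = interval.x0_lo + (interval.x0_hi - interval.x0_lo) * rng.uniform(
        size=interval.x0_lo.shape
    )
    nom = interval.nominal
    return LinearCompartmentalModel(A=A, b=nom.b, c=c, x0=x0, labels=nom.labels)


def _load_manifest() -> dict:
    with resources.files("pkbound.data").joinpath("manifest.json").open() as fh:
        return json.load(fh)


def _load_table1() -> dict[str, np.ndarray]:
    path = resources.files("pkbound.data").joinpath("table1.csv")
    with path.open() as fh:
        header = fh.readline().strip().split(",")
        rows = [line.strip().split(",") for line in fh if line.strip()]
    cols = {name: np.array([float(r[i]) for r in rows]) for i, name in enumerate(header)}
    return cols


def fixture_metadata() -> dict:
    """The shipped manifest: provenance and notes for every reference dataset."""
    return _load_manifest()


def fixtures() -> dict:
    """Named reference datasets from the source study.

    Returns a dict with:

    - ``table1_no_tenside_conc_mg_per_ml``, ``table1_no_tenside_mg``,
      ``table1_tenside_mg``: the in vivo sample series as :class:`SampleSeries`;
    - ``params_{two,three}_compartment_{no_tenside,tenside}``: identified
      rate-constant sets (1/h) as dicts;
    - ``matrix_*`` / ``interval_*``: the printed nominal and ±10% bound
      matrices as dicts of arrays (the known misprint in the two-compartment
      lower bound is corrected; see the manifest note);
    - ``dose_mg``, ``blood_volume_ml``: scalars.
    """
    manifest = _load_manifest()
    cols = _load_table1()
    t = cols["time_h"]
    out: dict = {
        "table1_no_tenside_conc_mg_per_ml": SampleSeries(
            t, cols["conc_no_tenside_mg_per_ml"], unit="mg_per_ml", label="no tenside (conc)"
        ),
        "table1_no_tenside_mg": SampleSeries(
            t, cols["amount_no_tenside_mg"], unit="mg", label="no tenside (amount)"
        ),
        "table1_tenside_mg": SampleSeries(
            t, cols["amount_tenside_mg"], unit="mg", label="tenside (amount)"
        ),
        "dose_mg": manifest["dose_mg"],
        "blood_volume_ml": manifest["blood_volume_ml"],
    }
    for name, params in manifest["params"].items():
        out[f"params_{name}"] = dict(params)
    for name, mats in manifest["matrices"].items():
        out[name] = {
            k: np.asarray(v, dtype=float) for k, v in mats.items() if not k.endswith("note")
        }
    return out
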