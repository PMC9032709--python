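"""Reading and writing of sample series, trajectories, envelopes and model configs.

All delimited-text I/O uses a mandatory header row; sample files carry columns
``time_h,value``.  Readers tolerate comma or semicolon delimiters; numbers are
written with 6 significant digits.  Unit tags are mandatory on sample series so
amounts (mg) and concentrations (mg/mL) can never be mixed silently.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .models import (
    IntervalModel,
    LinearCompartmentalModel,
    UncertaintySpec,
    build_three_compartment,
    build_two_compartment,
)
from .simulate import EnvelopePair, Trajectory
from .synthetic import SampleSeries

__all__ = [
    "read_samples",
    "write_samples",
    "write_trajectory",
    "write_envelope",
    "read_envelope",
    "read_model_config",
]

_FMT = "{:.6g}"


def _split_line(line: str) -> list[str]:
    delim = ";" if (";" in line and "," not in line) else ","
    return [cell.strip() for cell in line.rstrip("\n").split(delim)]


def read_samples(path, unit: str = "mg", label: str | None = None) -> SampleSeries:
    """Read a ``time_h,value`` CSV (comma- or semicolon-delimited) into a SampleSeries."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = _split_line(lines[0])
    if len(header) < 2 or header[0] != "time_h":
        raise ValueError(
            f"{path}:1: malformed header {header!r}; expected 'time_h,value'"
        )
    times, values = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = _split_line(line)
        if len(cells) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(cells)}")
        try:
            t, v = float(cells[0]), float(cells[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
        if v < 0:
            raise ValueError(f"{path}:{lineno}: negative value {v}")
        times.append(t)
        values.append(v)
    try:
        return SampleSeries(
            times=np.array(times),
            values=np.array(values),
            unit=unit,
            label=label if label is not None else header[1],
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_samples(series: SampleSeries, path) -> None:
    """Write a SampleSeries as ``time_h,value`` CSV with 6 significant digits."""
    lines = ["time_h,value"]
    for t, v in zip(series.times, series.values):
        lines.append(f"{_FMT.format(t)},{_FMT.format(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as CSV: ``time_h`` plus one column per compartment label."""
    labels = traj.labels or tuple(f"x{i + 1}" for i in range(traj.n))
    lines = ["time_h," + ",".join(labels)]
    for k in range(traj.times.size):
        row = [_FMT.format(traj.times[k])] + [_FMT.format(v) for v in traj.states[k]]
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_envelope(env: EnvelopePair, path) -> None:
    """Write an envelope as CSV with ``_lo``/``_hi`` suffixed columns per compartment."""
    labels = env.lower.labels or tuple(f"x{i + 1}" for i in range(env.lower.n))
    header = ["time_h"]
    for lab in labels:
        header += [f"{lab}_lo", f"{lab}_hi"]
    lines = [",".join(header)]
    for k in range(env.times.size):
        row = [_FMT.format(env.times[k])]
        for i in range(env.lower.n):
            row += [_FMT.format(env.lower.states[k, i]), _FMT.format(env.upper.states[k, i])]
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_envelope(path) -> EnvelopePair:
    """Read an envelope CSV written by :func:`write_envelope`."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    header = _split_line(lines[0])
    if header[0] != "time_h" or len(header) < 3 or (len(header) - 1) % 2:
        raise ValueError(f"{path}:1: malformed envelope header {header!r}")
    labels = tuple(name[:-3] for name in header[1::2])
    for pos, name in enumerate(header[1:], start=1):
        expected = "_lo" if pos % 2 else "_hi"
        if not name.endswith(expected):
            raise ValueError(f"{path}:1: column {name!r} should end with {expected!r}")
    data = np.array([[float(c) for c in _split_line(ln)] for ln in lines[1:]])
    times = data[:, 0]
    lo_states = data[:, 1::2]
    hi_states = data[:, 2::2]
    lower = Trajectory(times, lo_states, np.zeros_like(times), labels)
    upper = Trajectory(times, hi_states, np.zeros_like(times), labels)
    return EnvelopePair(lower=lower, upper=upper)


def read_model_config(path) -> tuple[LinearCompartmentalModel, UncertaintySpec]:
    """Read a YAML/JSON model configuration.

    Schema (YAML is a superset of JSON, so either syntax works)::

        structure: two_compartment | three_compartment | explicit
        rates: {ka: ..., ke1: ..., ke2: ...}       # or ka/ke1/k23/ke3
        dose_mg: 50
        observed_compartment: 2                    # 1-based
        delta: 0.1
        x0_delta: 0.0
        # explicit structure instead supplies:
        A: [[...], ...]
        c: [...]
        x0: [...]
        labels: [...]
    """
    path = Path(path)
    with path.open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "structure" not in cfg:
        raise ValueError(f"{path}: config must be a mapping with a 'structure' key")
    structure = cfg["structure"]
    delta = float(cfg.get("delta", 0.0))
    x0_delta = float(cfg.get("x0_delta", 0.0))
    spec = UncertaintySpec(delta=delta, x0_delta=x0_delta)
    if structure == "explicit":
        for key in ("A", "c", "x0"):
            if key not in cfg:
                raise ValueError(f"{path}: explicit structure requires key {key!r}")
        model = LinearCompartmentalModel(
            A=np.array(cfg["A"], dtype=float),
            b=np.array(cfg.get("b", np.zeros(len(cfg["x0"]))), dtype=float),
            c=np.array(cfg["c"], dtype=float),
            x0=np.array(cfg["x0"], dtype=float),
            labels=tuple(cfg.get("labels", ())),
        )
        return model, spec
    rates = cfg.get("rates")
    if not isinstance(rates, dict):
        raise ValueError(f"{path}: key 'rates' (mapping of rate constants) is required")
    dose = float(cfg.get("dose_mg", 0.0))
    if structure == "two_compartment":
        model = build_two_compartment(
            ka=float(rates["ka"]), ke1=float(rates["ke1"]), ke2=float(rates["ke2"]), dose=dose
        )
    elif structure == "three_compartment":
        model = build_three_compartment(
            ka=float(rates["ka"]),
            ke1=float(rates["ke1"]),
            k23=float(rates["k23"]),
            ke3=float(rates["ke3"]),
            dose=dose,
            observed=int(cfg.get("observed_compartment", 3)),
        )
    else:
        raise ValueError(
            f"{path}: unknown structure {structure!r}; "
            "use two_compartment, three_compartment or explicit"
        )
    return model, spec
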