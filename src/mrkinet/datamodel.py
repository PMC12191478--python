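"""Domain types and timecourse I/O.

The central container is :class:`Timecourse`: concentrations (or CIELAB
color coordinates) of named responses sampled at increasing times during
an isothermal evaporation run.  Files are plain CSV with a ``time_min``
column and one column per response; each response header carries its unit
in brackets, e.g. ``glucose[g/g DS]``.  Times are stored in minutes (the
sampling convention of the experiments); kinetic fits convert to hours
internally so rate constants come out in h^-1.

Units are carried as opaque tags and never converted automatically:
mixing ``g/g DS`` with ``ug/g DS`` in arithmetic is an error, because the
network rate constants silently absorb unit scale.
"""

from __future__ import annotations

import io
import json
import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: Recognized unit tags.  ``color`` marks dimensionless CIELAB coordinates,
#: which are exempt from the nonnegativity check (a* may be negative).
UNIT_TAGS = ("g/g DS", "mg/g DS", "ug/g DS", "color")

#: Aliases accepted on input (the micro sign normalizes to ASCII ``u``).
_UNIT_ALIASES = {
    "µg/g DS": "ug/g DS",
    "μg/g DS": "ug/g DS",
    "dimensionless": "color",
    "-": "color",
}

TIME_COLUMN = "time_min"


def _canonical_unit(tag: str) -> str:
    tag = tag.strip()
    tag = _UNIT_ALIASES.get(tag, tag)
    if tag not in UNIT_TAGS:
        raise ValidationError(
            f"unknown unit tag {tag!r}; expected one of {UNIT_TAGS}"
        )
    return tag


@dataclass(frozen=True)
class ResponseSeries:
    """A single measured response: name, values and unit tag."""

    name: str
    values: tuple[float, ...]
    unit: str

    def __post_init__(self):
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        object.__setattr__(self, "unit", _canonical_unit(self.unit))
        if not self.name:
            raise ValidationError("response name must be nonempty")
        if any(not math.isfinite(v) for v in self.values):
            raise ValidationError(f"response {self.name!r} has non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def is_color(self) -> bool:
        return self.unit == "color"


@dataclass(frozen=True)
class Timecourse:
    """Sampled responses vs. time at one nominal temperature.

    Parameters
    ----------
    temperature : float
        Nominal process temperature in degrees Celsius.
    times : sequence of float
        Sampling times in minutes, strictly increasing, first >= 0.
    responses : mapping of str -> ResponseSeries
        One series per response, all the same length as ``times``.
    """

    temperature: float
    times: tuple[float, ...]
    responses: Mapping[str, ResponseSeries] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        if len(self.times) == 0:
            raise ValidationError("timecourse needs at least one sampling time")
        if self.times[0] < 0:
            raise ValidationError("first sampling time must be >= 0")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValidationError("sampling times must be strictly increasing")
        if not math.isfinite(self.temperature):
            raise ValidationError("temperature must be finite")
        resp = dict(self.responses)
        for name, series in resp.items():
            if not isinstance(series, ResponseSeries):
                series = ResponseSeries(name, tuple(series), "g/g DS")
                resp[name] = series
            if len(series) != len(self.times):
                raise ValidationError(
                    f"response {name!r} has {len(series)} values for "
                    f"{len(self.times)} times"
                )
            if not series.is_color:
                for i, v in enumerate(series.values):
                    if v < 0:
                        raise ValidationError(
                            f"negative concentration at row {i}, column {name!r}"
                        )
        object.__setattr__(self, "responses", resp)

    @property
    def n_points(self) -> int:
        return len(self.times)

    def response_names(self) -> list[str]:
        return list(self.responses)

    def to_frame(self) -> pd.DataFrame:
        data = {TIME_COLUMN: list(self.times)}
        for name, series in self.responses.items():
            data[f"{name}[{series.unit}]"] = list(series.values)
        return pd.DataFrame(data)


@dataclass
class RunConfig:
    """Configuration for synthetic-study generation and network fitting.

    Defaults reproduce the study design: four evaporation temperatures,
    a 30 min run sampled every 5 min, 5% multiplicative measurement noise.
    """

    temperatures: tuple[float, ...] = (60.0, 70.0, 80.0, 90.0)
    times_min: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
    noise_cv: float = 0.05
    seed: int = 0
    rtol: float = 1e-8
    atol_scale: float = 1e-12
    multistarts: int = 16
    #: upper box bounds for rate constants, keyed k1..k15; unset keys use
    #: ``default_upper``.  The wide bounds for k8/k15 (and k10/k13) reflect
    #: the orders of magnitude the dehydration steps are known to span.
    upper_bounds: dict = field(default_factory=lambda: {
        "k8": 1e6, "k15": 1e6, "k10": 1e3, "k13": 1e3,
    })
    default_upper: float = 1e2
    #: effective zero for log-space optimization (h^-1)
    log_floor: float = 1e-7

    def __post_init__(self):
        self.temperatures = tuple(float(t) for t in self.temperatures)
        self.times_min = tuple(float(t) for t in self.times_min)
        for t in self.temperatures:
            if not 0.0 < t < 150.0:
                raise ValidationError(f"temperature {t} outside (0, 150) C")
        if not 0.0 <= self.noise_cv < 1.0:
            raise ValidationError("noise_cv must be in [0, 1)")
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise ValidationError("seed must be a nonnegative integer")
        if self.multistarts < 1:
            raise ValidationError("multistarts must be >= 1")

    def upper_for(self, param: str) -> float:
        return float(self.upper_bounds.get(param, self.default_upper))

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["temperatures"] = list(self.temperatures)
        d["times_min"] = list(self.times_min)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        try:
            d = json.loads(text)
        except json.JSONDecodeError as exc:
            raise FormatError(f"invalid RunConfig JSON: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise FormatError(f"unknown RunConfig keys: {sorted(unknown)}")
        return cls(**d)


def _parse_header(col: str) -> tuple[str, str]:
    col = col.strip()
    if not col.endswith("]") or "[" not in col:
        raise FormatError(
            f"column {col!r} lacks a unit suffix like 'glucose[g/g DS]'"
        )
    name, _, rest = col.partition("[")
    return name.strip(), _canonical_unit(rest[:-1])


def read_timecourse(path: str | os.PathLike | io.TextIOBase,
                    temperature: float = float("nan")) -> Timecourse:
    """Read a Timecourse CSV.

    The file must have a ``time_min`` column; every other column is a
    response whose header carries a bracketed unit tag.  Rows are sorted
    by time before validation.  A ``# temperature_C = <value>`` comment on
    the first line, if present, overrides the ``temperature`` argument.
    """
    if isinstance(path, io.TextIOBase):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    lines = text.splitlines()
    if lines and lines[0].startswith("#"):
        head = lines[0].lstrip("#").strip()
        if head.startswith("temperature_C"):
            temperature = float(head.split("=", 1)[1])
        lines = lines[1:]
    try:
        df = pd.read_csv(io.StringIO("\n".join(lines)))
    except Exception as exc:  # pandas raises several parser error types
        raise FormatError(f"could not parse CSV: {exc}") from exc
    if TIME_COLUMN not in df.columns:
        raise FormatError(f"missing required column {TIME_COLUMN!r}")
    if df.shape[1] < 2:
        raise FormatError("no response columns found")
    df = df.sort_values(TIME_COLUMN, kind="stable").reset_index(drop=True)
    times = df[TIME_COLUMN].to_numpy(dtype=float)
    responses = {}
    for col in df.columns:
        if col == TIME_COLUMN:
            continue
        name, unit = _parse_header(col)
        values = df[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(values)):
            raise ValidationError(f"non-finite value in column {col!r}")
        if unit != "color":
            bad = np.where(values < 0)[0]
            if bad.size:
                raise ValidationError(
                    f"negative concentration at row {int(bad[0])}, "
                    f"column {name!r}"
                )
        responses[name] = ResponseSeries(name, tuple(values), unit)
    if isinstance(temperature, float) and math.isnan(temperature):
        temperature = 25.0  # nominal ambient when the file does not say
    return Timecourse(temperature=temperature, times=tuple(times),
                      responses=responses)


def write_timecourse(tc: Timecourse, path: str | os.PathLike) -> str:
    """Write a Timecourse to CSV; inverse of :func:`read_timecourse`.

    Values are printed at full ``repr`` precision so that
    ``read(write(tc))`` reproduces them bit-for-bit.
    """
    if not tc.responses:
        raise ValidationError("timecourse has no responses; nothing to write")
    lines = [f"# temperature_C = {tc.temperature!r}"]
    headers = [TIME_COLUMN] + [
        f"{name}[{s.unit}]" for name, s in tc.responses.items()
    ]
    lines.append(",".join(headers))
    for i, t in enumerate(tc.times):
        row = [repr(t)] + [repr(s.values[i]) for s in tc.responses.values()]
        lines.append(",".join(row))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
    return str(path)
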