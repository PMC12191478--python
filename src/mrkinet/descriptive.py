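"""Descriptive color and composition metrics.

CIELAB total color difference dE* between a sample and its pre-evaporation
reference, the perceivability categories used in sensory practice, and the
percent-change / group-sum arithmetic used to summarize substrate
consumption and product accumulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .datamodel import Timecourse
from .errors import ValidationError


@dataclass(frozen=True)
class ColorState:
    """CIELAB coordinates: L* lightness, a* green-red, b* blue-yellow."""

    L: float
    a: float
    b: float

    def __post_init__(self):
        for v in (self.L, self.a, self.b):
            if not math.isfinite(v):
                raise ValidationError("color components must be finite")
        if not 0.0 <= self.L <= 100.0:
            raise ValidationError(f"L* = {self.L} outside [0, 100]")


def delta_e(current: ColorState, reference: ColorState) -> float:
    """Euclidean CIELAB color difference dE* between two states.

    Symmetric in its arguments and zero iff the states coincide.
    """
    return math.sqrt(
        (current.L - reference.L) ** 2
        + (current.a - reference.a) ** 2
        + (current.b - reference.b) ** 2
    )


#: Perceivability bands for dE*, half-open [lo, hi); boundary values fall
#: in the higher category.  Differences >= 6 are beyond the tabulated scale.
PERCEIVABILITY_BANDS = (
    (0.0, 0.5, "not_noticeable"),
    (0.5, 1.5, "slightly_noticeable"),
    (1.5, 3.0, "noticeable"),
    (3.0, 6.0, "highly_visible"),
)


def perceivability(de: float) -> str:
    """Categorize a color difference into the standard sensory bands."""
    if not math.isfinite(de) or de < 0:
        raise ValidationError(f"delta E must be finite and >= 0, got {de}")
    for lo, hi, label in PERCEIVABILITY_BANDS:
        if lo <= de < hi:
            return label
    return "beyond_scale"


def percent_change(c_start: float, c_end: float) -> float:
    """Signed percent change 100*(c_end - c_start)/c_start.

    Both values must be in the same unit; ``c_start`` must be positive.
    A consumption rate is the negation of this value when the response
    decreases (see :func:`consumption_rate`).
    """
    if not (math.isfinite(c_start) and math.isfinite(c_end)):
        raise ValidationError("concentrations must be finite")
    if c_start <= 0:
        raise ValidationError(f"c_start must be > 0, got {c_start}")
    return 100.0 * (c_end - c_start) / c_start


def consumption_rate(c_start: float, c_end: float) -> float:
    """Percent of the starting amount consumed: 100*(c_start - c_end)/c_start."""
    return -percent_change(c_start, c_end)


def group_sum(values: Sequence[float], units: Iterable[str] | None = None) -> float:
    """Sum of concentrations sharing a unit (e.g. an amino-acid class total)."""
    values = list(values)
    if not values:
        raise ValidationError("group_sum needs a nonempty list")
    if units is not None:
        units = set(units)
        if len(units) > 1:
            raise ValidationError(f"mixed units in group_sum: {sorted(units)}")
    return float(math.fsum(float(v) for v in values))


def describe_timecourse(tc: Timecourse) -> "pd.DataFrame":
    """Per-response percent change (first -> last sample) and, for color
    responses, dE* of every sample against the first row.

    Returns a DataFrame with one row per response: columns ``response``,
    ``unit``, ``start``, ``end``, ``percent_change`` (NaN where the start
    value is nonpositive).  If all of L*, a*, b* are present a dE* column
    block is appended as extra rows named ``dE*@<time>``.
    """
    import pandas as pd

    rows = []
    for name, s in tc.responses.items():
        start, end = s.values[0], s.values[-1]
        pc = percent_change(start, end) if start > 0 else float("nan")
        rows.append({"response": name, "unit": s.unit,
                     "start": start, "end": end, "percent_change": pc})
    color_names = [n for n in ("L*", "a*", "b*") if n in tc.responses]
    if len(color_names) == 3:
        Ls, as_, bs = (tc.responses[n].values for n in ("L*", "a*", "b*"))
        ref = ColorState(Ls[0], as_[0], bs[0])
        for i, t in enumerate(tc.times):
            de = delta_e(ColorState(Ls[i], as_[i], bs[i]), ref)
            rows.append({"response": f"dE*@{t:g}min", "unit": "color",
                         "start": np.nan, "end": de,
                         "percent_change": np.nan})
    return pd.DataFrame(rows)
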