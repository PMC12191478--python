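"""Synthetic timecourse generation emulating the MCSJ model-system study.

The generator forward-simulates the published network rate constants at
the four study temperatures (60-90 C) from the model-system recipe
(sucrose 12.475, fructose 0.441, glucose 0.514 g/100 mL at 15 Brix,
converted to a per-gram-dry-solids basis), samples a 30 min evaporation
every 5 min, and applies multiplicative Gaussian measurement noise
truncated at zero — the error structure of triplicate chromatographic /
colorimetric assays.  Amino acids are not state variables (their
availability is absorbed into the pseudo-first-order constants); they are
recorded in the study manifest only.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import published
from .datamodel import ResponseSeries, RunConfig, Timecourse, write_timecourse
from .errors import ValidationError
from .network import (RateConstants, build_mcsj_network, simulate,
                      SPECIES, SPECIES_RESPONSE_NAMES)
from .simple_kinetics import MINUTES_PER_HOUR


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement noise model: none, or multiplicative Gaussian with the
    given coefficient of variation, truncated so values stay >= 0."""

    kind: str = "none"
    cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("none", "multiplicative_gaussian"):
            raise ValidationError(f"unknown noise kind {self.kind!r}")
        if self.cv < 0:
            raise ValidationError("cv must be >= 0")
        if self.kind == "none" and self.cv != 0:
            raise ValidationError("kind 'none' requires cv = 0")
        if self.seed < 0:
            raise ValidationError("seed must be nonnegative")

    def apply(self, values: np.ndarray, rng: np.random.Generator,
              clip_zero: bool = True) -> np.ndarray:
        if self.kind == "none" or self.cv == 0:
            return np.asarray(values, dtype=float).copy()
        eps = rng.normal(0.0, self.cv, size=np.shape(values))
        noisy = np.asarray(values, dtype=float) * (1.0 + eps)
        return np.clip(noisy, 0.0, None) if clip_zero else noisy


def simple_series_closed_form(order: int, k: float, C0: float,
                              times_min: Sequence[float]) -> np.ndarray:
    """Noise-free integrated rate law evaluated at the given times."""
    t_h = np.asarray(times_min, dtype=float) / MINUTES_PER_HOUR
    if order == 0:
        return C0 + k * t_h
    if order == 1:
        return C0 * np.exp(k * t_h)
    if order == 2:
        denom = 1.0 / C0 + k * t_h
        if np.any(denom <= 0):
            raise ValidationError(
                "second-order trajectory diverges within the sampled window"
            )
        return 1.0 / denom
    raise ValidationError(f"order must be 0, 1 or 2, got {order}")


def generate_simple_series(order: int, k: float, C0: float,
                           times_min: Sequence[float],
                           noise: NoiseSpec = NoiseSpec(),
                           name: str = "response",
                           unit: str = "g/g DS") -> ResponseSeries:
    """Sample one simple-order trajectory, optionally with noise.

    Color responses (unit ``"color"``) may go negative under a negative
    zero-order slope; concentration responses may not, and raise instead.
    """
    if order in (1, 2) and C0 <= 0:
        raise ValidationError("C0 must be > 0 for orders 1 and 2")
    clean = simple_series_closed_form(order, k, C0, times_min)
    is_color = unit == "color"
    if not is_color and np.any(clean < 0):
        raise ValidationError(
            "zero-order parameters produce negative concentrations; "
            "use a color unit if this is a color coordinate"
        )
    rng = np.random.default_rng(noise.seed)
    values = noise.apply(clean, rng, clip_zero=not is_color)
    return ResponseSeries(name, tuple(values), unit)


def default_initial_state() -> np.ndarray:
    """Model-system initial state on a per-g-dry-solids basis.

    The recipe's dissolved solids are the weighed components themselves,
    so each sugar is divided by their total; reaction intermediates and
    products start at zero, as does the latent enediol.
    """
    comp = published.MODEL_SYSTEM_COMPOSITION
    total = sum(comp.values())
    y0 = np.zeros(len(SPECIES))
    y0[SPECIES.index("SUC")] = comp["sucrose"] / total
    y0[SPECIES.index("FRU")] = comp["fructose"] / total
    y0[SPECIES.index("GLU")] = comp["glucose"] / total
    return y0


def generate_network_timecourse(k: RateConstants, y0: Sequence[float],
                                times_min: Sequence[float],
                                noise: NoiseSpec = NoiseSpec(),
                                hide_latent: bool = True,
                                rtol: float = 1e-10,
                                atol_scale: float = 1e-14) -> Timecourse:
    """Forward-simulate the network and apply per-response noise.

    ``hide_latent`` (default) drops the unobservable 1,2-enediol column,
    mimicking real data in which the enolization intermediate cannot be
    quantified.
    """
    network = build_mcsj_network()
    clean = simulate(network, k, y0, times_min, rtol=rtol,
                     atol_scale=atol_scale, method="expm")
    rng = np.random.default_rng(noise.seed)
    responses = {}
    latent_name = SPECIES_RESPONSE_NAMES["ED"]
    for name, series in clean.responses.items():
        if hide_latent and name == latent_name:
            continue
        values = noise.apply(np.asarray(series.values), rng)
        responses[name] = ResponseSeries(name, tuple(values), series.unit)
    return Timecourse(temperature=clean.temperature, times=clean.times,
                      responses=responses)


def generate_study_bundle(config: RunConfig,
                          outdir: str | os.PathLike | None = None
                          ) -> tuple[dict[float, Timecourse], dict]:
    """One network timecourse per study temperature, plus a manifest.

    Rate constants are the published per-temperature estimates; the child
    seed for each temperature is derived from ``config.seed`` so the whole
    bundle replays byte-identically from the manifest.  When ``outdir`` is
    given, each timecourse is written as ``model_system_<T>C.csv`` next to
    ``manifest.json``.
    """
    y0 = default_initial_state()
    bundle: dict[float, Timecourse] = {}
    manifest = {
        "seed": int(config.seed),
        "noise_cv": config.noise_cv,
        "times_min": list(config.times_min),
        "initial_state": {sp: float(v) for sp, v in zip(SPECIES, y0)},
        "amino_acids_g_per_100mL": {
            n: published.MODEL_SYSTEM_COMPOSITION[n]
            for n in ("proline", "histidine", "lysine")
        },
        "temperatures": {},
    }
    kind = "multiplicative_gaussian" if config.noise_cv > 0 else "none"
    for i, temp in enumerate(config.temperatures):
        k = RateConstants.from_dict(published.network_k_values(temp), temp)
        child_seed = int(config.seed) * 1000 + i
        noise = NoiseSpec(kind=kind, cv=config.noise_cv, seed=child_seed)
        tc = generate_network_timecourse(k, y0, config.times_min, noise)
        bundle[temp] = tc
        manifest["temperatures"][f"{temp:g}"] = {
            "seed": child_seed,
            "rate_constants": k.as_dict(),
            "file": f"model_system_{temp:g}C.csv",
        }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for temp, tc in bundle.items():
            write_timecourse(tc, outdir / f"model_system_{temp:g}C.csv")
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return bundle, manifest
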