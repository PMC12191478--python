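"""The 11-species, 15-step melanoidin-formation network and its ODE model.

Species
-------
SUC sucrose, GLU glucose, FRU fructose, ED 1,2-enediol (unobserved
enolization intermediate), DG3 3-deoxyglucosone, HMF5
5-hydroxymethylfurfural, GO glyoxal, MGO methylglyoxal, CML
carboxymethyl-lysine, CEL carboxyethyl-lysine, MEL melanoidins.

Every step is pseudo-first-order in its single substrate (amino-acid
availability is absorbed into the rate constant), so the mass-action
system is linear, dy/dt = M(k) y, with M a Metzler matrix whose columns
encode the fate of each species.  This linearity is exploited throughout:
the trajectory has the closed form y(t) = expm(M t) y0, which serves both
as a fast propagator for estimation and as an independent cross-check of
the stiff solver (the rate constants span seven orders of magnitude, so
the system is severely stiff).

Concentration units are per-species (sugars g/g dry solids, downstream
products ug/g DS, ED a dimensionless latent); the rate constants are
unit-bearing and absorb the conversion between substrate and product
scales.  No automatic unit conversion is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .datamodel import ResponseSeries, Timecourse
from .errors import IntegrationError, ValidationError
from .simple_kinetics import MINUTES_PER_HOUR

#: Canonical species order of the state vector.
SPECIES = ("SUC", "GLU", "FRU", "ED", "DG3", "HMF5",
           "GO", "MGO", "CML", "CEL", "MEL")

#: Human-readable response names used in Timecourse tables, per species.
SPECIES_RESPONSE_NAMES = {
    "SUC": "sucrose", "GLU": "glucose", "FRU": "fructose",
    "ED": "1,2-enediol", "DG3": "3-DG", "HMF5": "5-HMF",
    "GO": "GO", "MGO": "MGO", "CML": "CML", "CEL": "CEL",
    "MEL": "melanoidins",
}
RESPONSE_TO_SPECIES = {v: k for k, v in SPECIES_RESPONSE_NAMES.items()}

#: Measurement unit per species (ED is a dimensionless latent).
SPECIES_UNITS = {
    "SUC": "g/g DS", "GLU": "g/g DS", "FRU": "g/g DS", "ED": "color",
    "DG3": "ug/g DS", "HMF5": "ug/g DS", "GO": "ug/g DS", "MGO": "ug/g DS",
    "CML": "ug/g DS", "CEL": "ug/g DS", "MEL": "ug/g DS",
}

PARAM_NAMES = tuple(f"k{i}" for i in range(1, 16))


@dataclass(frozen=True)
class Reaction:
    """One pseudo-first-order step: substrate -> products (unit stoichiometry)."""

    id: str
    substrate: str
    products: tuple[str, ...]


@dataclass(frozen=True)
class ReactionNetwork:
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]

    def __post_init__(self):
        declared = set(self.species)
        for r in self.reactions:
            if r.substrate not in declared:
                raise ValidationError(f"{r.id}: unknown substrate {r.substrate}")
            for p in r.products:
                if p not in declared:
                    raise ValidationError(f"{r.id}: unknown product {p}")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def index(self, species: str) -> int:
        return self.species.index(species)


@dataclass(frozen=True)
class RateConstants:
    """The 15 rate constants (h^-1, unit-bearing) at one temperature."""

    k: tuple[float, ...]
    temperature: float = float("nan")

    def __post_init__(self):
        object.__setattr__(self, "k", tuple(float(v) for v in self.k))
        if len(self.k) != 15:
            raise ValidationError(f"expected 15 rate constants, got {len(self.k)}")
        if any(v < 0 or not np.isfinite(v) for v in self.k):
            raise ValidationError("rate constants must be finite and >= 0")

    @classmethod
    def from_dict(cls, d: Mapping[str, float],
                  temperature: float = float("nan")) -> "RateConstants":
        missing = [p for p in PARAM_NAMES if p not in d]
        if missing:
            raise ValidationError(f"missing rate constants: {missing}")
        return cls(tuple(float(d[p]) for p in PARAM_NAMES), temperature)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(PARAM_NAMES, self.k))


#: (reaction id, substrate, products) for the 15 elementary steps:
#: sucrose hydrolysis, glucose/fructose enolization to the 1,2-enediol and
#: back, dehydration of the enediol to 3-DG, the two 5-HMF routes, retro-
#: aldol cleavage of 3-DG to the short-chain dicarbonyls, AGE formation,
#: and the three melanoidin-forming steps.
_REACTION_TABLE = (
    ("k1", "SUC", ("GLU", "FRU")),
    ("k2", "ED", ("FRU",)),
    ("k3", "FRU", ("ED",)),
    ("k4", "ED", ("GLU",)),
    ("k5", "GLU", ("ED",)),
    ("k6", "ED", ("DG3",)),
    ("k7", "FRU", ("HMF5",)),
    ("k8", "DG3", ("HMF5",)),
    ("k9", "DG3", ("GO",)),
    ("k10", "DG3", ("MGO",)),
    ("k11", "GO", ("CML",)),
    ("k12", "CML", ("MEL",)),
    ("k13", "MGO", ("CEL",)),
    ("k14", "CEL", ("MEL",)),
    ("k15", "HMF5", ("MEL",)),
)


def build_mcsj_network() -> ReactionNetwork:
    """The canonical melanoidin-formation network of the MCSJ model system."""
    return ReactionNetwork(
        species=SPECIES,
        reactions=tuple(Reaction(i, s, p) for i, s, p in _REACTION_TABLE),
    )


def matrix_form(network: ReactionNetwork, k: RateConstants) -> np.ndarray:
    """Rate matrix M with dy/dt = M y.

    M[i][i] is minus the total rate constant leaving species i; M[j][i]
    sums the rate constants of steps i -> j.  Off-diagonals are
    nonnegative (Metzler structure), which guarantees trajectories from a
    nonnegative state stay nonnegative.
    """
    n = network.n_species
    M = np.zeros((n, n))
    for kj, r in zip(k.k, network.reactions):
        i = network.index(r.substrate)
        M[i, i] -= kj
        for p in r.products:
            M[network.index(p), i] += kj
    return M


def rhs(state: Sequence[float], k: RateConstants,
        network: ReactionNetwork | None = None,
        neg_tol: float = 1e-9) -> np.ndarray:
    """Mass-action time derivative at ``state`` (per hour)."""
    network = network or build_mcsj_network()
    y = np.asarray(state, dtype=float)
    if y.shape != (network.n_species,):
        raise ValidationError(
            f"state must have {network.n_species} components, got {y.shape}"
        )
    scale = max(float(np.max(np.abs(y))), 1.0)
    if np.any(y < -neg_tol * scale):
        raise ValidationError("negative state component beyond tolerance")
    return matrix_form(network, k) @ y


def propagate_expm(network: ReactionNetwork, k: RateConstants,
                   y0: Sequence[float], times_min: Sequence[float]) -> np.ndarray:
    """Exact trajectory of the linear system via the matrix exponential.

    Returns an array of shape (n_times, n_species).  Exact up to the
    accuracy of ``scipy.linalg.expm``; preferred inside estimation loops,
    where it is both faster and more accurate than step-wise integration.
    """
    y0 = np.asarray(y0, dtype=float)
    t_h = np.asarray(times_min, dtype=float) / MINUTES_PER_HOUR
    M = matrix_form(network, k)
    out = np.empty((t_h.size, y0.size))
    # propagate between successive output times; equal spacings share expm
    cache: dict[float, np.ndarray] = {}
    y = y0.copy()
    t_prev = 0.0
    for i, t in enumerate(t_h):
        dt = t - t_prev
        if dt > 0:
            P = cache.get(dt)
            if P is None:
                P = expm(M * dt)
                cache[dt] = P
            y = P @ y
        out[i] = y
        t_prev = t
    return out


def simulate(network: ReactionNetwork, k: RateConstants,
             y0: Sequence[float], times_min: Sequence[float],
             rtol: float = 1e-8, atol_scale: float = 1e-12,
             method: str = "Radau") -> Timecourse:
    """Integrate the network forward and return a Timecourse.

    Parameters
    ----------
    times_min : sequence of float
        Output times in minutes, increasing, first >= 0.
    rtol, atol_scale : float
        Solver tolerances; the absolute tolerance is ``atol_scale`` times
        the largest initial concentration.
    method : str
        ``"Radau"`` or ``"BDF"`` (implicit, required by the stiffness of
        the system) or ``"expm"`` for the closed-form matrix-exponential
        propagator.

    Tiny negative excursions (within solver tolerance) are clipped to
    zero; anything larger raises :class:`IntegrationError`.
    """
    y0 = np.asarray(y0, dtype=float)
    if y0.shape != (network.n_species,):
        raise ValidationError(
            f"y0 must have {network.n_species} components, got {y0.shape}"
        )
    if np.any(y0 < 0):
        raise ValidationError("initial state must be nonnegative")
    times_min = np.asarray(times_min, dtype=float)
    if times_min.size == 0 or times_min[0] < 0 or np.any(np.diff(times_min) <= 0):
        raise ValidationError("times must be increasing and start at >= 0")

    scale = max(float(y0.max()), 1e-30)
    if method == "expm":
        ys = propagate_expm(network, k, y0, times_min)
    else:
        M = matrix_form(network, k)
        t_h = times_min / MINUTES_PER_HOUR
        sol = solve_ivp(
            lambda t, y: M @ y, (0.0, float(t_h[-1])), y0,
            method=method, t_eval=t_h, rtol=rtol, atol=atol_scale * scale,
            jac=lambda t, y: M,
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed: {sol.message}",
                t_fail=float(sol.t[-1]) * MINUTES_PER_HOUR if sol.t.size else None,
            )
        ys = sol.y.T
    neg_floor = -1e-6 * scale
    if np.any(ys < neg_floor):
        t_bad = float(times_min[np.any(ys < neg_floor, axis=1).argmax()])
        raise IntegrationError(
            "trajectory went negative beyond tolerance", t_fail=t_bad
        )
    ys = np.clip(ys, 0.0, None)

    responses = {}
    for j, sp in enumerate(network.species):
        name = SPECIES_RESPONSE_NAMES[sp]
        responses[name] = ResponseSeries(name, tuple(ys[:, j]),
                                         SPECIES_UNITS[sp])
    temp = k.temperature if np.isfinite(k.temperature) else 25.0
    return Timecourse(temperature=temp, times=tuple(times_min),
                      responses=responses)
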