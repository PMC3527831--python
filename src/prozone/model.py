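"""Equilibrium scaffold-occupancy model of a multi-kinase scaffold.

A scaffold protein S carries one binding site per kinase of a cascade
(canonically Raf, MEK and ERK). Each kinase X binds its site reversibly and,
by assumption, independently of the other sites, so a pairwise mass-balance
equation per kinase determines the bound amount SX::

    (S_T - SX) * (X_T - SX) / SX = K_D

with S_T, X_T the total scaffold and kinase amounts and K_D = k_off / k_on.
The occupancy probability p(X bound) = SX / S_T, and the level of scaffolds
carrying a *complete* cascade is the independence product

    full_complex(S_T) = S_T * prod_i p_i(S_T).

Titrating S_T produces the prozone (a.k.a. "combinatorial inhibition")
curve: full complexes rise with scaffold up to the least abundant kinase,
stay near-maximal up to the second-least abundant kinase, then decline as
excess scaffold sequesters kinases into incomplete complexes. The optimal
scaffold level is therefore a *range* framed by the two scarcest kinases,
not a point — unless all kinases are equally abundant.

The module is organised in the order the analysis runs:

1.  constants, errors, domain types;
2.  pairwise equilibrium and titration curves (the analytic model);
3.  finite-copy-number oracles: exact placement combinatorics, exact
    finite-K_D enumeration, stochastic simulation, mass-action ODE;
4.  range analysis: plateau extraction, closed forms, configuration counts;
5.  scenario generation, presets, unit conversion, file I/O and pipeline.

Amounts are in arbitrary consistent units (totals and K_D must share units)
or integer copy numbers; nothing inside the core converts units.
"""

from __future__ import annotations

import hashlib
import io
import itertools
import json
import logging
import math
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import constants as _constants
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.special import gammaln

__all__ = [
    # errors
    "ProzoneError", "DomainError", "ValidationError", "ConfigurationError",
    "CapacityError", "ConvergenceError",
    # types
    "LigandSpec", "ScaffoldScenario", "BindingRates", "OccupancyResult",
    "TitrationCurve", "CountDistribution", "DiscreteAssemblyState",
    "SsaResult", "SsaTrace", "OptimalRange", "ConfigurationCount",
    "ScenarioGeneratorConfig", "CellScenario",
    # equilibrium core
    "solve_pairwise_equilibrium", "occupancy_probability",
    "full_complex_level", "titration_curve", "default_grid",
    "tight_binding_full_complex",
    # oracles
    "tight_binding_placement", "enumerate_tight_placements",
    "conditional_full_complex_distribution",
    "designated_scaffold_hit_probability", "exact_finite_kd_expectation",
    "ssa_stationary_mean", "mass_action_steady_state",
    # range analysis
    "optimal_range_from_curve", "tight_binding_range", "max_full_complexes",
    "configuration_count", "stoichiometry_scan",
    # scenarios & I/O
    "generate_scenarios", "canonical_presets", "copies_to_concentration",
    "concentration_to_copies", "hela_scenario", "load_scenario",
    "save_scenario", "curve_to_csv", "scan_to_csv", "run_pipeline",
    "AVOGADRO", "ENUMERATION_GUARD",
]

logger = logging.getLogger("prozone")

AVOGADRO: float = _constants.Avogadro

#: Largest copy number (scaffolds or any ligand) accepted by the exact
#: finite-K_D enumeration; above it the falling-factorial sums are better
#: served by the stochastic simulator.
ENUMERATION_GUARD: int = 30

#: Default plateau threshold: the optimal range is where the full-complex
#: level is within this fraction of its maximum.
DEFAULT_THRESHOLD: float = 0.95

#: Default titration grid: log-spaced points from 0.01x to 100x the largest
#: ligand total, wide enough to show both prozone flanks.
DEFAULT_GRID_POINTS: int = 200
DEFAULT_GRID_SPAN: tuple[float, float] = (0.01, 100.0)


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------

class ProzoneError(Exception):
    """Base class for all errors raised by this package."""


class DomainError(ProzoneError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ValidationError(ProzoneError, ValueError):
    """A scenario or file failed structural validation."""


class ConfigurationError(ProzoneError):
    """A required configuration value is missing (never silently defaulted)."""


class CapacityError(ProzoneError):
    """Problem size exceeds an exact method's guard; use a sampling oracle."""


class ConvergenceError(ProzoneError, RuntimeError):
    """An iterative solver failed to reach its tolerance within budget."""


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if math.isnan(value) or math.isinf(value):
        raise DomainError(f"{name} must be finite, got {value!r}")
    return value


def _require_nonneg(name: str, value: float) -> float:
    value = _require_finite(name, value)
    if value < 0:
        raise DomainError(f"{name} must be >= 0, got {value!r}")
    return value


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LigandSpec:
    """One kinase species: its total amount and scaffold-site K_D.

    ``total`` and ``kd`` share the scenario's unit system (arbitrary
    concentration units or copies).
    """

    name: str
    total: float
    kd: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("ligand name must be nonempty")
        _require_nonneg(f"total({self.name})", self.total)
        _require_nonneg(f"kd({self.name})", self.kd)


@dataclass(frozen=True)
class ScaffoldScenario:
    """Full parameterization of the model: scaffold total plus ligand list.

    ``units`` is a bookkeeping tag ({'arbitrary-concentration' | 'copies'});
    the core treats all amounts as dimensionless-consistent.
    """

    s_total: float
    ligands: tuple[LigandSpec, ...]
    units: str = "arbitrary-concentration"

    def __post_init__(self) -> None:
        _require_nonneg("s_total", self.s_total)
        object.__setattr__(self, "ligands", tuple(self.ligands))
        if len(self.ligands) < 1:
            raise ValidationError("scenario needs at least one ligand")
        names = [lig.name for lig in self.ligands]
        if len(set(names)) != len(names):
            raise ValidationError(f"ligand names must be unique, got {names}")
        if self.units not in ("arbitrary-concentration", "copies"):
            raise ValidationError(f"unknown units tag {self.units!r}")

    @property
    def totals(self) -> tuple[float, ...]:
        return tuple(lig.total for lig in self.ligands)

    @property
    def kds(self) -> tuple[float, ...]:
        return tuple(lig.kd for lig in self.ligands)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(lig.name for lig in self.ligands)

    def with_s_total(self, s_total: float) -> "ScaffoldScenario":
        return replace(self, s_total=float(s_total))

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "s_total": self.s_total,
            "units": self.units,
            "ligands": [
                {"name": lig.name, "total": lig.total, "kd": lig.kd}
                for lig in self.ligands
            ],
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, data: Mapping) -> "ScaffoldScenario":
        for key in ("s_total", "ligands"):
            if key not in data:
                raise ValidationError(f"scenario JSON missing required field {key!r}")
        ligands = []
        for i, entry in enumerate(data["ligands"]):
            for key in ("name", "total", "kd"):
                if key not in entry:
                    raise ValidationError(
                        f"ligands[{i}] missing required field {key!r}")
            ligands.append(LigandSpec(entry["name"], entry["total"], entry["kd"]))
        return cls(
            s_total=data["s_total"],
            ligands=tuple(ligands),
            units=data.get("units", "arbitrary-concentration"),
        )

    @classmethod
    def from_json(cls, text: str) -> "ScaffoldScenario":
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"invalid scenario JSON: {exc}") from exc
        return cls.from_dict(data)


@dataclass(frozen=True)
class BindingRates:
    """Kinetic parameterization of one site: k_on and k_off, K_D = k_off/k_on."""

    kon: float
    koff: float

    def __post_init__(self) -> None:
        if not (_require_finite("kon", self.kon) > 0):
            raise DomainError(f"kon must be > 0, got {self.kon!r}")
        _require_nonneg("koff", self.koff)

    @property
    def kd(self) -> float:
        return self.koff / self.kon

    @classmethod
    def from_kd(cls, kd: float, kon: float = 1.0) -> "BindingRates":
        return cls(kon=kon, koff=_require_nonneg("kd", kd) * kon)

    def check_consistent(self, kd: float, rtol: float = 1e-9) -> None:
        """Raise unless koff/kon matches ``kd`` within relative tolerance."""
        if abs(self.kd - kd) > rtol * max(abs(kd), 1e-300):
            if not (kd == 0 and self.koff == 0):
                raise DomainError(
                    f"rates imply K_D={self.kd!r} but ligand specifies {kd!r}")


@dataclass(frozen=True)
class OccupancyResult:
    """Equilibrium state at one scaffold total: per-ligand bound amounts SX,
    occupancy probabilities SX/S_T, and the full-complex level."""

    bound: tuple[float, ...]
    p_bound: tuple[float, ...]
    full_complex: float


@dataclass(frozen=True)
class TitrationCurve:
    """Occupancy results over a strictly increasing grid of scaffold totals.

    The embedded scenario's ``s_total`` field is ignored; the grid replaces it.
    """

    s_grid: tuple[float, ...]
    results: tuple[OccupancyResult, ...]
    scenario: ScaffoldScenario

    def __post_init__(self) -> None:
        if len(self.s_grid) != len(self.results):
            raise ValidationError("s_grid and results length mismatch")
        grid = np.asarray(self.s_grid, dtype=float)
        if len(grid) and not np.all(np.diff(grid) > 0):
            raise ValidationError("s_grid must be strictly increasing")

    @property
    def full_complex(self) -> np.ndarray:
        return np.array([r.full_complex for r in self.results])

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, list[float]] = {"s_total": list(self.s_grid)}
        for i, name in enumerate(self.scenario.names):
            data[f"p_bound_{name}"] = [r.p_bound[i] for r in self.results]
        data["full_complex"] = [r.full_complex for r in self.results]
        return pd.DataFrame(data)


@dataclass(frozen=True)
class CountDistribution:
    """Probability mass function over integer counts (e.g. full complexes)."""

    values: tuple[int, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        total = math.fsum(self.probs)
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"distribution sums to {total!r}, not 1")
        if any(p < -1e-15 for p in self.probs):
            raise ValidationError("negative probability mass")

    @property
    def expectation(self) -> float:
        return math.fsum(v * p for v, p in zip(self.values, self.probs))

    def pmf(self, value: int) -> float:
        try:
            return self.probs[self.values.index(value)]
        except ValueError:
            return 0.0


@dataclass(frozen=True)
class DiscreteAssemblyState:
    """Finite-copy-number equilibrium: per-ligand bound-count marginals.

    Ligands occupy sites independently, so the joint distribution over
    bound-count vectors (b_1, ..., b_L) factorizes over the marginals.
    ``kd_dimensionless`` is expressed in copies per unit volume (volume 1),
    so analytic and discrete parameterizations coincide numerically.
    """

    n_scaffold: int
    copies: tuple[int, ...]
    kd_dimensionless: tuple[float, ...]
    marginals: tuple[tuple[float, ...], ...]
    expected_full_complexes: float

    @property
    def expected_bound(self) -> tuple[float, ...]:
        return tuple(
            math.fsum(b * p for b, p in enumerate(marg))
            for marg in self.marginals
        )

    def joint(self) -> np.ndarray:
        """Joint pmf over bound-count vectors, axis i indexed by b_i."""
        out = np.array([1.0])
        for marg in self.marginals:
            out = np.multiply.outer(out, np.asarray(marg))
        return out[0] if out.ndim > len(self.marginals) else out

    def distribution(self) -> dict[tuple[int, ...], float]:
        joint = self.joint()
        return {
            idx: float(joint[idx])
            for idx in np.ndindex(joint.shape)
            if joint[idx] > 0
        }


@dataclass(frozen=True)
class SsaTrace:
    """Event log of a stochastic binding/unbinding run."""

    times: tuple[float, ...]
    bound_counts: tuple[tuple[int, ...], ...]
    seed: int
    n_scaffold: int
    ligand_names: tuple[str, ...] = ()

    def to_csv(self, path=None) -> str | None:
        names = self.ligand_names or tuple(
            f"L{i + 1}" for i in range(len(self.bound_counts[0]))
        )
        buf = io.StringIO()
        buf.write(f"# seed={self.seed}\n")
        buf.write("time," + ",".join(f"bound_{n}" for n in names)
                  + ",full_complexes\n")
        # full_complexes: expected intersection size given the counts
        norm = self.n_scaffold ** (len(names) - 1)
        for t, counts in zip(self.times, self.bound_counts):
            buf.write(f"{t:.12g}," + ",".join(str(c) for c in counts))
            buf.write(f",{math.prod(counts) / norm:.12g}\n")
        text = buf.getvalue()
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None


@dataclass(frozen=True)
class SsaResult:
    """Time-averaged stationary summary of a stochastic run."""

    mean_bound: tuple[float, ...]
    mean_full_complexes: float
    se_bound: tuple[float, ...]
    se_full_complexes: float
    n_events: int
    seed: int
    trace: SsaTrace | None = None


@dataclass(frozen=True)
class OptimalRange:
    """Scaffold interval over which full complexes stay within ``threshold``
    of the peak, plus the peak value itself."""

    lower: float
    upper: float
    peak_value: float
    threshold: float
    method: str  # {"grid", "tight_binding_analytic"}

    def __post_init__(self) -> None:
        if self.lower > self.upper * (1 + 1e-12):
            raise ValidationError("range lower exceeds upper")

    @property
    def width_ratio(self) -> float:
        return self.upper / self.lower if self.lower > 0 else math.inf


@dataclass(frozen=True)
class ConfigurationCount:
    """Number of distinguishable scaffold species given per-site states and
    oligomerization order (combinatorial-explosion bookkeeping)."""

    n_sites: int
    states_per_site: int
    oligomer_order: int
    count: int


@dataclass(frozen=True)
class ScenarioGeneratorConfig:
    """Sampling ranges for the synthetic-scenario generator: log-uniform
    totals and K_Ds, reproducible under ``seed``."""

    seed: int
    n_ligands: int = 3
    total_range: tuple[float, float] = (0.1, 100.0)
    kd_range: tuple[float, float] = (0.01, 10.0)

    def __post_init__(self) -> None:
        if self.n_ligands < 1:
            raise DomainError("n_ligands must be >= 1")
        for label, (lo, hi) in (("total_range", self.total_range),
                                ("kd_range", self.kd_range)):
            if not (lo <= hi):
                raise DomainError(f"{label} must satisfy lo <= hi, got {lo, hi}")
            if lo < 0:
                raise DomainError(f"{label} must be nonnegative")
        if self.total_range[0] <= 0:
            raise DomainError("total_range lower bound must be positive")
        lo, hi = self.kd_range
        if lo == 0 and hi > 0:
            raise DomainError(
                "kd_range with zero lower bound must be degenerate (0, 0); "
                "log-uniform sampling needs a positive lower bound")


@dataclass(frozen=True)
class CellScenario:
    """Cell-scale amounts with explicit per-species units and a volume, so
    copies and molar concentrations interconvert without a hidden default."""

    volume: float  # liters
    species: Mapping[str, tuple[float, str]]  # name -> (value, 'copies'|'molar')

    def __post_init__(self) -> None:
        if not (self.volume > 0):
            raise DomainError(f"volume must be > 0 L, got {self.volume!r}")
        for name, (value, unit) in self.species.items():
            if unit not in ("copies", "molar"):
                raise ValidationError(f"{name}: unknown unit {unit!r}")
            _require_nonneg(name, value)

    def molar(self, name: str) -> float:
        value, unit = self.species[name]
        return value if unit == "molar" else copies_to_concentration(value, self.volume)

    def copies(self, name: str) -> int:
        value, unit = self.species[name]
        return int(value) if unit == "copies" else concentration_to_copies(value, self.volume)


# --------------------------------------------------------------------------
# Pairwise equilibrium and titration (the analytic model)
# --------------------------------------------------------------------------

def solve_pairwise_equilibrium(s_total: float, x_total: float, kd: float) -> float:
    """Bound amount SX for one scaffold site and one ligand at equilibrium.

    Solves the mass balance (S_T - SX)(X_T - SX) = K_D * SX, i.e. the
    quadratic SX^2 - (S_T + X_T + K_D) SX + S_T X_T = 0, returning the
    physical (smaller) root in [0, min(S_T, X_T)].

    Uses the numerically stable form ``SX = 2 S_T X_T / (b + sqrt(b^2 -
    4 S_T X_T))`` with b = S_T + X_T + K_D, which avoids catastrophic
    cancellation when K_D is much smaller than the totals. K_D = 0 is the
    tight-binding limit and returns min(S_T, X_T) exactly.
    """
    s = _require_nonneg("s_total", s_total)
    x = _require_nonneg("x_total", x_total)
    kd = _require_nonneg("kd", kd)
    if s == 0.0 or x == 0.0:
        return 0.0
    if kd == 0.0:
        return min(s, x)
    b = s + x + kd
    disc = b * b - 4.0 * s * x
    # disc = (s - x)^2 + kd^2 + 2 kd (s + x) >= 0 always; guard roundoff.
    root = 2.0 * s * x / (b + math.sqrt(max(disc, 0.0)))
    return min(root, s, x)


def occupancy_probability(s_total: float, x_total: float, kd: float) -> float:
    """Fraction of scaffolds carrying ligand X: p(X bound) = SX / S_T."""
    s = _require_nonneg("s_total", s_total)
    if s == 0.0:
        raise DomainError("occupancy probability undefined at s_total = 0")
    p = solve_pairwise_equilibrium(s, x_total, kd) / s
    return min(max(p, 0.0), 1.0)


def full_complex_level(scenario: ScaffoldScenario) -> OccupancyResult:
    """Level of fully occupied scaffolds under the independence product.

    Each ligand's occupancy is computed from its own pairwise equilibrium
    (sites do not interact), and the probability that a scaffold carries the
    complete cascade is the product of single-site occupancies::

        full_complex = S_T * prod_i p_bound_i
    """
    s = scenario.s_total
    if s == 0.0:
        zeros = tuple(0.0 for _ in scenario.ligands)
        return OccupancyResult(bound=zeros, p_bound=zeros, full_complex=0.0)
    bound = tuple(
        solve_pairwise_equilibrium(s, lig.total, lig.kd)
        for lig in scenario.ligands
    )
    p_bound = tuple(min(b / s, 1.0) for b in bound)
    full = s * math.prod(p_bound)
    return OccupancyResult(bound=bound, p_bound=p_bound, full_complex=full)


def default_grid(scenario: ScaffoldScenario,
                 n_points: int = DEFAULT_GRID_POINTS) -> tuple[float, float, int]:
    """Default titration span: 0.01x to 100x the largest ligand total."""
    top = max(scenario.totals)
    if top <= 0:
        raise DomainError("default grid needs a positive ligand total")
    return (DEFAULT_GRID_SPAN[0] * top, DEFAULT_GRID_SPAN[1] * top, n_points)


def titration_curve(scenario: ScaffoldScenario,
                    s_min: float | None = None,
                    s_max: float | None = None,
                    n_points: int = DEFAULT_GRID_POINTS,
                    spacing: str = "log") -> TitrationCurve:
    """Evaluate the full-complex level over a grid of scaffold totals."""
    if s_min is None or s_max is None:
        lo, hi, _ = default_grid(scenario, n_points)
        s_min = lo if s_min is None else s_min
        s_max = hi if s_max is None else s_max
    if not (0 < s_min < s_max):
        raise DomainError(f"need 0 < s_min < s_max, got ({s_min!r}, {s_max!r})")
    if n_points < 2:
        raise DomainError(f"n_points must be >= 2, got {n_points!r}")
    if spacing == "log":
        grid = np.geomspace(s_min, s_max, n_points)
    elif spacing == "linear":
        grid = np.linspace(s_min, s_max, n_points)
    else:
        raise DomainError(f"spacing must be 'log' or 'linear', got {spacing!r}")
    grid[0], grid[-1] = s_min, s_max  # endpoints exact
    results = tuple(
        full_complex_level(scenario.with_s_total(float(s))) for s in grid
    )
    return TitrationCurve(s_grid=tuple(float(s) for s in grid),
                          results=results, scenario=scenario)


def tight_binding_full_complex(s_total: float, totals: Sequence[float]) -> float:
    """Closed-form full-complex level in the tight-binding limit (K_D = 0).

    With sorted totals x_1 <= ... <= x_L each occupancy is min(S_T, x_i)/S_T,
    so the level is piecewise: S_T below x_1, then successively x_1,
    x_1 x_2 / S_T, x_1 x_2 x_3 / S_T^2, ... as S_T crosses each total.
    """
    s = _require_nonneg("s_total", s_total)
    xs = sorted(_require_nonneg("total", x) for x in totals)
    if s == 0.0:
        return 0.0
    return s * math.prod(min(s, x) / s for x in xs)


# --------------------------------------------------------------------------
# Finite-copy-number oracles
# --------------------------------------------------------------------------
#
# The discrete placement semantics (the reading under which the worked
# integer example holds): each scaffold has one site per ligand type, every
# ligand copy occupies a distinct scaffold, and placements are uniform over
# scaffolds with a free matching site. Ligand types place independently.

def _placement_sizes(n_scaffold: int, copies: Sequence[int]) -> list[int]:
    if n_scaffold < 1:
        raise DomainError(f"n_scaffold must be >= 1, got {n_scaffold!r}")
    sizes = []
    for c in copies:
        if c < 0 or int(c) != c:
            raise DomainError(f"copies must be nonnegative integers, got {c!r}")
        sizes.append(min(n_scaffold, int(c)))
    if not sizes:
        raise DomainError("need at least one ligand")
    return sizes


def tight_binding_placement(n_scaffold: int,
                            copies: Sequence[int]) -> CountDistribution:
    """Exact distribution of the number of fully occupied scaffolds when
    every ligand binds tightly (K_D = 0).

    Per ligand i, m_i = min(n_scaffold, copies_i) distinct scaffolds are
    occupied, chosen uniformly; types are independent. The full-complex
    count is the size of the intersection of the L occupied subsets, whose
    pmf follows by folding hypergeometric intersections one ligand at a
    time (computed in exact rational arithmetic).
    """
    sizes = _placement_sizes(n_scaffold, copies)
    n = int(n_scaffold)
    dist: dict[int, Fraction] = {sizes[0]: Fraction(1)}
    for m in sizes[1:]:
        new: dict[int, Fraction] = {}
        denom = math.comb(n, m)
        for j, p in dist.items():
            for k in range(max(0, j + m - n), min(j, m) + 1):
                w = Fraction(math.comb(j, k) * math.comb(n - j, m - k), denom)
                new[k] = new.get(k, Fraction(0)) + p * w
        dist = new
    values = tuple(sorted(dist))
    probs = tuple(float(dist[v]) for v in values)
    return CountDistribution(values=values, probs=probs)


def enumerate_tight_placements(n_scaffold: int, copies: Sequence[int],
                               max_placements: int = 2_000_000):
    """Exhaustively yield (placement, probability) over all joint tight-binding
    placements; each placement is a tuple of frozensets of occupied scaffolds.

    Brute-force counterpart of :func:`tight_binding_placement`, intended for
    small systems and cross-validation.
    """
    sizes = _placement_sizes(n_scaffold, copies)
    n = int(n_scaffold)
    n_joint = math.prod(math.comb(n, m) for m in sizes)
    if n_joint > max_placements:
        raise CapacityError(
            f"{n_joint} joint placements exceed the enumeration cap")
    prob = 1.0 / n_joint
    pools = [
        [frozenset(c) for c in itertools.combinations(range(n), m)]
        for m in sizes
    ]
    for combo in itertools.product(*pools):
        yield combo, prob


def conditional_full_complex_distribution(
        n_scaffold: int, copies: Sequence[int],
        hitter: int = 0, vacant: int = 1) -> CountDistribution:
    """Full-complex distribution *conditioned* on a copy of ligand ``hitter``
    occupying some scaffold left unoccupied by ligand ``vacant``.

    This is the discrete worked case "Raf binds the scaffold that misses
    MEK": with one scaffold more than MEK copies, exactly one scaffold lacks
    MEK, and if a Raf lands there only one of the two possible full
    complexes can form. Computed by exhaustive enumeration.
    """
    mass: dict[int, float] = {}
    total = 0.0
    for combo, prob in enumerate_tight_placements(n_scaffold, copies):
        missed = set(range(n_scaffold)) - combo[vacant]
        if not (combo[hitter] & missed):
            continue
        full = len(frozenset.intersection(*combo))
        mass[full] = mass.get(full, 0.0) + prob
        total += prob
    if total == 0.0:
        raise DomainError(
            "conditioning event has probability zero for these counts")
    values = tuple(sorted(mass))
    probs = tuple(mass[v] / total for v in values)
    return CountDistribution(values=values, probs=probs)


def designated_scaffold_hit_probability(n_scaffold: int, k_copies: int,
                                        form: str = "designated_copy") -> float:
    """Probability that a designated scaffold receives a ligand copy under
    uniform distinct placement of ``k_copies`` copies on ``n_scaffold``
    scaffolds.

    Two readings are exposed and neither is preferred:

    - ``'designated_copy'``: one *particular* copy lands on the designated
      scaffold; equals 1/n by symmetry (the printed worked value, 1/6 for
      2 copies on 6 scaffolds).
    - ``'any_copy'``: *some* copy lands there; equals
      1 - C(n-1, k)/C(n, k) = k/n (1/3 in the same worked case).
    """
    n, k = int(n_scaffold), int(k_copies)
    if n < 1:
        raise DomainError(f"n_scaffold must be >= 1, got {n_scaffold!r}")
    if not (0 <= k <= n):
        raise DomainError(f"need 0 <= k_copies <= n_scaffold, got {k_copies!r}")
    if form == "designated_copy":
        return 1.0 / n
    if form == "any_copy":
        return k / n
    raise DomainError(f"form must be 'designated_copy' or 'any_copy', got {form!r}")


def exact_finite_kd_expectation(
        n_scaffold: int, copies: Sequence[int],
        kd_dimensionless: float | Sequence[float]) -> DiscreteAssemblyState:
    """Exact finite-copy-number equilibrium at finite K_D by enumeration.

    Per ligand with c copies, the equilibrium pmf over the bound count b is

        w(b) ∝ C(n, b) * c! / (c - b)! * kappa^b,   kappa = 1 / K_D,

    the partition-function weight for choosing b occupied scaffolds and
    pairing them with b of the c copies (K_D in copies per unit volume,
    volume 1). K_D = 0 degenerates to a point mass at min(n, c). Ligands are
    independent, and given counts the occupied subsets are uniform, so the
    expected number of full complexes is (prod_i E[b_i]) / n^(L-1).

    Counts above the enumeration guard raise :class:`CapacityError`; use
    :func:`ssa_stationary_mean` for larger systems.
    """
    sizes = _placement_sizes(n_scaffold, copies)
    n = int(n_scaffold)
    copies = [int(c) for c in copies]
    if max([n, *copies]) > ENUMERATION_GUARD:
        raise CapacityError(
            f"counts exceed the enumeration guard ({ENUMERATION_GUARD}); "
            "use ssa_stationary_mean for larger systems")
    kds = (list(kd_dimensionless) if isinstance(kd_dimensionless, (list, tuple, np.ndarray))
           else [float(kd_dimensionless)] * len(copies))
    if len(kds) != len(copies):
        raise DomainError("one kd per ligand required")
    marginals: list[tuple[float, ...]] = []
    for c, m, kd in zip(copies, sizes, kds):
        _require_nonneg("kd", kd)
        if kd == 0.0:
            marg = np.zeros(m + 1)
            marg[m] = 1.0
        else:
            b = np.arange(m + 1)
            logw = (
                gammaln(n + 1) - gammaln(b + 1) - gammaln(n - b + 1)  # C(n,b)
                + gammaln(c + 1) - gammaln(c - b + 1)                  # c!/(c-b)!
                - b * math.log(kd)                                      # kappa^b
            )
            logw -= logw.max()
            marg = np.exp(logw)
            marg /= marg.sum()
        marginals.append(tuple(float(p) for p in marg))
    e_bound = [
        math.fsum(b * p for b, p in enumerate(marg)) for marg in marginals
    ]
    expected_full = math.prod(e_bound) / n ** (len(copies) - 1)
    return DiscreteAssemblyState(
        n_scaffold=n, copies=tuple(copies),
        kd_dimensionless=tuple(float(k) for k in kds),
        marginals=tuple(marginals),
        expected_full_complexes=expected_full,
    )


def ssa_stationary_mean(n_scaffold: int, copies: Sequence[int],
                        rates: Sequence[BindingRates],
                        horizon: float, burn_in: float | None = None,
                        seed: int = 0, record_trace: bool = False,
                        n_batches: int = 20) -> SsaResult:
    """Stochastic simulation of per-site binding/unbinding; time-averaged
    stationary means after burn-in.

    State: per-ligand bound count b_i. Propensities (volume 1): binding
    k_on,i (c_i - b_i)(n - b_i), unbinding k_off,i b_i. Direct-method SSA
    with a single global event clock; reproducible given ``seed``. The mean
    full-complex level is the time average of prod_i b_i / n^(L-1) (the
    expected intersection size given counts, by placement symmetry), and
    standard errors come from batch means over the post-burn-in window.
    """
    sizes = _placement_sizes(n_scaffold, copies)
    n = int(n_scaffold)
    copies = [int(c) for c in copies]
    L = len(copies)
    if len(rates) != L:
        raise DomainError("one BindingRates per ligand required")
    if burn_in is None:
        burn_in = 0.2 * horizon
    if not (horizon > burn_in >= 0):
        raise DomainError(f"need horizon > burn_in >= 0, got "
                          f"({horizon!r}, {burn_in!r})")
    kon = np.array([r.kon for r in rates])
    koff = np.array([r.koff for r in rates])
    b = np.zeros(L, dtype=int)

    def propensities() -> np.ndarray:
        a = np.empty(2 * L)
        a[:L] = kon * (np.array(copies) - b) * (n - b)
        a[L:] = koff * b
        return a

    if propensities().sum() == 0.0:
        raise DomainError("all propensities are zero for the initial state; "
                          "degenerate input (no copies or no scaffolds?)")

    rng = np.random.default_rng(seed)
    t = 0.0
    n_events = 0
    times: list[float] = [0.0]
    states: list[tuple[int, ...]] = [tuple(b)]
    edges = np.linspace(burn_in, horizon, n_batches + 1)
    batch_b = np.zeros((n_batches, L))
    batch_full = np.zeros(n_batches)

    def accumulate(t0: float, t1: float, state: np.ndarray) -> None:
        """Credit dwell time in [t0, t1) to the overlapped batches."""
        if t1 <= burn_in:
            return
        t0 = max(t0, burn_in)
        i0 = min(np.searchsorted(edges, t0, side="right") - 1, n_batches - 1)
        i1 = min(np.searchsorted(edges, t1, side="right") - 1, n_batches - 1)
        full = math.prod(int(x) for x in state) / n ** (L - 1)
        for i in range(i0, i1 + 1):
            dt = min(t1, edges[i + 1]) - max(t0, edges[i])
            if dt > 0:
                batch_b[i] += dt * state
                batch_full[i] += dt * full

    while t < horizon:
        a = propensities()
        a0 = a.sum()
        if a0 == 0.0:  # absorbed (e.g. koff = 0, everything bound)
            accumulate(t, horizon, b)
            t = horizon
            break
        dt = rng.exponential(1.0 / a0)
        t_next = t + dt
        if t_next >= horizon:
            accumulate(t, horizon, b)
            t = horizon
            break
        accumulate(t, t_next, b)
        r = int(rng.choice(2 * L, p=a / a0))
        if r < L:
            b[r] += 1
        else:
            b[r - L] -= 1
        t = t_next
        n_events += 1
        if record_trace:
            times.append(t)
            states.append(tuple(int(x) for x in b))

    batch_len = (horizon - burn_in) / n_batches
    mb = batch_b / batch_len
    mf = batch_full / batch_len
    mean_bound = mb.mean(axis=0)
    mean_full = mf.mean()
    se_bound = mb.std(axis=0, ddof=1) / math.sqrt(n_batches)
    se_full = mf.std(ddof=1) / math.sqrt(n_batches)
    trace = (SsaTrace(times=tuple(times), bound_counts=tuple(states),
                      seed=seed, n_scaffold=n)
             if record_trace else None)
    return SsaResult(
        mean_bound=tuple(float(x) for x in mean_bound),
        mean_full_complexes=float(mean_full),
        se_bound=tuple(float(x) for x in se_bound),
        se_full_complexes=float(se_full),
        n_events=n_events, seed=seed, trace=trace,
    )


def mass_action_steady_state(scenario: ScaffoldScenario,
                             rates: Sequence[BindingRates],
                             tol_factor: float = 1e-10,
                             max_chunks: int = 14) -> OccupancyResult:
    """Deterministic steady state of the full coupled binding system.

    Tracks every scaffold species indexed by its site-occupancy pattern
    (2^L species for L ligands) with mass-action binding/unbinding fluxes
    and free-ligand conservation, integrated stiffly over geometrically
    growing time spans until every derivative falls below
    ``tol_factor * max(totals)`` (an algebraic residual check, not just
    integrator convergence).

    For independent sites the marginals of this full system coincide with
    the pairwise quadratic solution — the independence product is exact in
    the deterministic limit — which makes this the ODE oracle for the
    analytic core.
    """
    L = len(scenario.ligands)
    if len(rates) != L:
        raise DomainError("one BindingRates per ligand required")
    for r, lig in zip(rates, scenario.ligands):
        r.check_consistent(lig.kd)
    totals = np.array(scenario.totals)
    kon = np.array([r.kon for r in rates])
    koff = np.array([r.koff for r in rates])
    n_species = 1 << L
    masks_with = [
        np.array([bool(mask & (1 << i)) for mask in range(n_species)])
        for i in range(L)
    ]

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        free = totals - np.array([y[m].sum() for m in masks_with])
        dy = np.zeros_like(y)
        for mask in range(n_species):
            for i in range(L):
                bit = 1 << i
                if mask & bit:
                    flux = koff[i] * y[mask]
                    dy[mask] -= flux
                    dy[mask ^ bit] += flux
                else:
                    flux = kon[i] * y[mask] * free[i]
                    dy[mask] -= flux
                    dy[mask | bit] += flux
        return dy

    scale = max(float(totals.max(initial=0.0)), scenario.s_total, 1e-300)
    tol = tol_factor * scale
    y = np.zeros(n_species)
    y[0] = scenario.s_total
    if scenario.s_total == 0.0:
        zeros = tuple(0.0 for _ in range(L))
        return OccupancyResult(bound=zeros, p_bound=zeros, full_complex=0.0)
    t_span = 1.0 / max(kon.max() * scale, koff.max(initial=0.0), 1e-12)
    for _ in range(max_chunks):
        sol = solve_ivp(rhs, (0.0, t_span), y, method="LSODA",
                        rtol=1e-12, atol=1e-14 * scale)
        if not sol.success:
            raise ConvergenceError(f"ODE integration failed: {sol.message}")
        y = sol.y[:, -1]
        if np.abs(rhs(0.0, y)).max() < tol:
            break
        t_span *= 10.0
    else:
        raise ConvergenceError(
            "mass-action system did not reach steady state within budget")
    bound = tuple(float(y[m].sum()) for m in masks_with)
    p_bound = tuple(min(b / scenario.s_total, 1.0) for b in bound)
    return OccupancyResult(bound=bound, p_bound=p_bound,
                           full_complex=float(y[n_species - 1]))


# --------------------------------------------------------------------------
# Range analysis
# --------------------------------------------------------------------------

def max_full_complexes(totals: Sequence[float]) -> float:
    """Upper bound on full complexes: the least abundant ligand's total."""
    totals = [_require_nonneg("total", t) for t in totals]
    if not totals:
        raise DomainError("need at least one ligand total")
    return min(totals)


def tight_binding_range(totals: Sequence[float]) -> OptimalRange:
    """Closed-form optimal scaffold range in the tight-binding limit:
    framed by the smallest and second-smallest ligand totals, with the
    smallest total as the peak full-complex level."""
    totals = [_require_finite("total", t) for t in totals]
    if len(totals) < 2:
        raise DomainError("tight-binding range needs at least two ligands")
    if any(t <= 0 for t in totals):
        raise DomainError("all ligand totals must be positive")
    xs = sorted(totals)
    return OptimalRange(lower=xs[0], upper=xs[1], peak_value=xs[0],
                        threshold=1.0, method="tight_binding_analytic")


def optimal_range_from_curve(curve: TitrationCurve,
                             threshold: float = DEFAULT_THRESHOLD) -> OptimalRange:
    """Extract the plateau [lower, upper] where full_complex >= threshold *
    max from a titration curve, refining both edges by root bracketing
    between adjacent grid points (continuous model evaluation) so the
    reported boundaries are grid-independent to ~1e-6 relative."""
    if not (0 < threshold <= 1):
        raise DomainError(f"threshold must be in (0, 1], got {threshold!r}")
    values = curve.full_complex
    if len(values) == 0:
        raise DomainError("empty titration curve")
    vmax = float(values.max())
    if vmax <= 0.0:
        raise DomainError("degenerate curve: full-complex level is zero "
                          "everywhere")
    target = threshold * vmax
    ok = values >= target * (1.0 - 1e-12)
    idx = np.flatnonzero(ok)
    first, last = int(idx[0]), int(idx[-1])
    grid = curve.s_grid

    def f(s: float) -> float:
        return full_complex_level(curve.scenario.with_s_total(s)).full_complex

    def refine(i_out: int, i_in: int) -> float:
        lo, hi = sorted((grid[i_out], grid[i_in]))
        g = lambda s: f(s) - target
        try:
            if g(lo) * g(hi) > 0:
                return grid[i_in]
            return brentq(g, lo, hi, rtol=1e-9)
        except ValueError:
            return grid[i_in]

    lower = grid[0] if first == 0 else refine(first - 1, first)
    upper = grid[-1] if last == len(grid) - 1 else refine(last + 1, last)
    return OptimalRange(lower=float(lower), upper=float(upper),
                        peak_value=vmax, threshold=threshold, method="grid")


def configuration_count(n_sites: int, states_per_site: int,
                        oligomer_order: int = 1) -> ConfigurationCount:
    """Number of distinguishable scaffold configurations: states^(sites *
    order), exact integer arithmetic.

    With three sites and three states per site (empty / bound /
    bound-phosphorylated) a monomer has 27 configurations and a dimer
    27 * 27 = 729 — the combinatorial explosion that makes fully detailed
    scaffold models hard to parameterize.
    """
    for label, v in (("n_sites", n_sites), ("states_per_site", states_per_site),
                     ("oligomer_order", oligomer_order)):
        if int(v) != v or v < 1:
            raise DomainError(f"{label} must be a positive integer, got {v!r}")
    count = int(states_per_site) ** (int(n_sites) * int(oligomer_order))
    return ConfigurationCount(n_sites=int(n_sites),
                              states_per_site=int(states_per_site),
                              oligomer_order=int(oligomer_order), count=count)


def stoichiometry_scan(ligand_sets: Sequence[Sequence[float]],
                       kds: Sequence[float],
                       s_min: float | None = None, s_max: float | None = None,
                       n_points: int = DEFAULT_GRID_POINTS,
                       threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Optimal range for every (ligand set, K_D) combination.

    Deterministic ordering: ligand set outer loop, K_D inner loop. Each row
    records the scenario, the extracted plateau and its peak.
    """
    if not len(ligand_sets) or not len(kds):
        raise DomainError("ligand_sets and kds must be nonempty")
    rows = []
    for totals in ligand_sets:
        for kd in kds:
            scenario = ScaffoldScenario(
                s_total=min(totals),
                ligands=tuple(
                    LigandSpec(f"L{i + 1}", float(t), float(kd))
                    for i, t in enumerate(totals)
                ),
            )
            curve = titration_curve(scenario, s_min, s_max, n_points)
            rng = optimal_range_from_curve(curve, threshold)
            rows.append({
                "ligand_totals": ";".join(f"{t:g}" for t in totals),
                "kd": float(kd),
                "threshold": threshold,
                "lower": rng.lower,
                "upper": rng.upper,
                "peak_value": rng.peak_value,
            })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Scenario generation, presets, units, I/O and pipeline
# --------------------------------------------------------------------------

def _log_uniform(rng: np.random.Generator, lo: float, hi: float,
                 size=None) -> np.ndarray | float:
    if lo == hi:
        return lo if size is None else np.full(size, lo)
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=size))


def generate_scenarios(config: ScenarioGeneratorConfig,
                       n: int) -> list[ScaffoldScenario]:
    """Draw ``n`` synthetic scenarios with log-uniform totals and K_Ds.

    Mimics the structure of the model's stoichiometry panels — a scaffold
    titrated against ligand pools of differing abundance — without any claim
    to biological correlation structure between the pools. Deterministic
    under the config seed; ligand names are auto-assigned L1..Lk.
    """
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n!r}")
    rng = np.random.default_rng(config.seed)
    out = []
    for _ in range(n):
        s_total = float(_log_uniform(rng, *config.total_range))
        totals = np.atleast_1d(
            _log_uniform(rng, *config.total_range, size=config.n_ligands))
        kds = np.atleast_1d(
            _log_uniform(rng, *config.kd_range, size=config.n_ligands))
        out.append(ScaffoldScenario(
            s_total=s_total,
            ligands=tuple(
                LigandSpec(f"L{i + 1}", float(t), float(k))
                for i, (t, k) in enumerate(zip(totals, kds))
            ),
        ))
    return out


_KINASES = ("Raf", "MEK", "ERK")


def _preset(totals: Sequence[float], kd: float,
            units: str = "arbitrary-concentration") -> ScaffoldScenario:
    return ScaffoldScenario(
        s_total=min(totals),
        ligands=tuple(LigandSpec(n, float(t), float(kd))
                      for n, t in zip(_KINASES, totals)),
        units=units,
    )


def canonical_presets() -> dict[str, ScaffoldScenario]:
    """The seven canonical stoichiometry presets.

    Six titration panels — ligand totals (2,2,2) and (2,10,20) at K_D 0.01
    (high affinity) and 1 (low affinity), and (2,100,200) at K_D 0.1 and 10 —
    plus the discrete worked example of 2 Raf, 5 MEK and 10 ERK copies at
    tight binding. The nominal s_total of each preset is the scarcest
    ligand's total (titrations ignore it).
    """
    return {
        "left_highaffinity": _preset((2, 2, 2), 0.01),
        "left_lowaffinity": _preset((2, 2, 2), 1.0),
        "mid_highaffinity": _preset((2, 10, 20), 0.01),
        "mid_lowaffinity": _preset((2, 10, 20), 1.0),
        "right_highaffinity": _preset((2, 100, 200), 0.1),
        "right_lowaffinity": _preset((2, 100, 200), 10.0),
        "discrete_worked": _preset((2, 5, 10), 0.0, units="copies"),
    }


def copies_to_concentration(copies: float, volume: float) -> float:
    """Convert a copy number to molar concentration in a volume (liters)."""
    if not (volume > 0):
        raise DomainError(f"volume must be > 0 L, got {volume!r}")
    return _require_nonneg("copies", copies) / (AVOGADRO * volume)


def concentration_to_copies(concentration: float, volume: float) -> int:
    """Inverse of :func:`copies_to_concentration`, rounded to whole copies."""
    if not (volume > 0):
        raise DomainError(f"volume must be > 0 L, got {volume!r}")
    return int(round(_require_nonneg("concentration", concentration)
                     * AVOGADRO * volume))


#: Literature-anchored HeLa kinase concentrations (molar): Raf ~13 nM,
#: MEK and ERK ~1 uM, i.e. a Raf:MEK ratio of about 1:100.
HELA_KINASE_MOLAR: dict[str, float] = {
    "Raf": 13e-9,
    "MEK": 1e-6,
    "ERK": 1e-6,
}

#: Measured KSR1 scaffold abundance in HeLa, copies per cell.
HELA_KSR1_COPIES: int = 1800


def hela_scenario(volume: float, scaffold_copies: int,
                  kds: Mapping[str, float] | Sequence[float] | None = None
                  ) -> ScaffoldScenario:
    """HeLa-like scenario: Raf 13 nM, MEK and ERK 1 uM, scaffold total from
    a copy number via the supplied cell volume.

    Scaffold-site dissociation constants for KSR1 are not established
    numbers, so ``kds`` is mandatory — there is no default to mistake for a
    measured value.
    """
    if kds is None:
        raise ConfigurationError(
            "hela_scenario requires explicit kds (per kinase, molar); "
            "no literature default exists for KSR1 site affinities")
    if isinstance(kds, Mapping):
        try:
            kd_list = [float(kds[k]) for k in _KINASES]
        except KeyError as exc:
            raise ConfigurationError(f"kds missing entry for {exc}") from exc
    else:
        kd_list = [float(k) for k in kds]
        if len(kd_list) != 3:
            raise ConfigurationError("kds sequence must have three entries "
                                     "(Raf, MEK, ERK)")
    s_total = copies_to_concentration(scaffold_copies, volume)
    return ScaffoldScenario(
        s_total=s_total,
        ligands=tuple(
            LigandSpec(name, HELA_KINASE_MOLAR[name], kd)
            for name, kd in zip(_KINASES, kd_list)
        ),
    )


# -- file I/O ---------------------------------------------------------------

def save_scenario(scenario: ScaffoldScenario, path) -> None:
    with open(path, "w") as fh:
        fh.write(scenario.to_json() + "\n")


def load_scenario(path) -> ScaffoldScenario:
    try:
        with open(path) as fh:
            text = fh.read()
    except OSError as exc:
        raise ProzoneError(f"cannot read scenario file {path}: {exc}") from exc
    return ScaffoldScenario.from_json(text)


def _fmt(value: float) -> str:
    return f"{value:.12g}"


def curve_to_csv(curve: TitrationCurve, path=None) -> str | None:
    """Serialize a titration curve: s_total, p_bound_<name>..., full_complex,
    floating values at 12 significant digits."""
    buf = io.StringIO()
    names = curve.scenario.names
    buf.write("s_total," + ",".join(f"p_bound_{n}" for n in names)
              + ",full_complex\n")
    for s, res in zip(curve.s_grid, curve.results):
        buf.write(",".join([_fmt(s), *(_fmt(p) for p in res.p_bound),
                            _fmt(res.full_complex)]) + "\n")
    text = buf.getvalue()
    if path is None:
        return text
    with open(path, "w") as fh:
        fh.write(text)
    return None


def scan_to_csv(table: pd.DataFrame, path=None) -> str | None:
    buf = io.StringIO()
    buf.write(",".join(table.columns) + "\n")
    for _, row in table.iterrows():
        cells = [
            str(row[c]) if not isinstance(row[c], float) else _fmt(row[c])
            for c in table.columns
        ]
        buf.write(",".join(cells) + "\n")
    text = buf.getvalue()
    if path is None:
        return text
    with open(path, "w") as fh:
        fh.write(text)
    return None


def run_pipeline(source, outdir, *,
                 s_min: float | None = None, s_max: float | None = None,
                 n_points: int = DEFAULT_GRID_POINTS, spacing: str = "log",
                 threshold: float = DEFAULT_THRESHOLD,
                 include_oracles: bool = False, seed: int = 0) -> dict:
    """Run the full analysis for one scenario and write report files.

    ``source`` is a :class:`ScaffoldScenario`, a preset name, or a path to a
    scenario JSON file. Writes ``titration.csv``, ``optimal_range.csv``,
    ``summary.json`` and ``pipeline.log`` into ``outdir``; all outputs are
    byte-identical on rerun with the same inputs and seed (the log carries
    no timestamps for this reason). Returns the summary dict.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)
        logger.info(msg)

    if isinstance(source, ScaffoldScenario):
        scenario = source
        log(f"scenario: inline ligands={scenario.names}")
    elif isinstance(source, str) and source in canonical_presets():
        scenario = canonical_presets()[source]
        log(f"scenario: preset {source}")
    else:
        scenario = load_scenario(source)
        log(f"scenario: file {source}")
    log(f"parameters: s_total={_fmt(scenario.s_total)} "
        f"totals={tuple(scenario.totals)} kds={tuple(scenario.kds)} "
        f"units={scenario.units} seed={seed}")

    second_smallest = sorted(scenario.totals)[1] if len(scenario.totals) > 1 else None
    if second_smallest is not None and scenario.s_total > second_smallest:
        log("warning: scaffold total exceeds the second-least-abundant "
            "ligand; operating on the prozone (declining) flank")

    curve = titration_curve(scenario, s_min, s_max, n_points, spacing)
    curve_to_csv(curve, outdir / "titration.csv")
    log(f"titration: {len(curve.s_grid)} points on "
        f"[{_fmt(curve.s_grid[0])}, {_fmt(curve.s_grid[-1])}] ({spacing})")

    rng = optimal_range_from_curve(curve, threshold)
    scan_to_csv(pd.DataFrame([{
        "ligand_totals": ";".join(f"{t:g}" for t in scenario.totals),
        "kd": scenario.kds[0] if len(set(scenario.kds)) == 1 else float("nan"),
        "threshold": threshold,
        "lower": rng.lower, "upper": rng.upper, "peak_value": rng.peak_value,
    }]), outdir / "optimal_range.csv")
    log(f"optimal range: [{_fmt(rng.lower)}, {_fmt(rng.upper)}] "
        f"peak={_fmt(rng.peak_value)} threshold={threshold}")

    oracle_checks: dict = {}
    if include_oracles:
        analytic_at_s = full_complex_level(scenario).full_complex if scenario.s_total > 0 else 0.0
        oracle_checks["analytic_full_complex_at_s_total"] = analytic_at_s
        counts_ok = (
            scenario.units == "copies"
            and all(float(t).is_integer() for t in scenario.totals)
            and scenario.s_total > 0 and float(scenario.s_total).is_integer()
            and max(scenario.s_total, *scenario.totals) <= ENUMERATION_GUARD
        )
        if counts_ok:
            n_sc = int(scenario.s_total)
            ints = [int(t) for t in scenario.totals]
            if all(k == 0 for k in scenario.kds):
                placement = tight_binding_placement(n_sc, ints)
                oracle_checks["discrete_expected_full_complexes"] = placement.expectation
            else:
                state = exact_finite_kd_expectation(n_sc, ints, list(scenario.kds))
                oracle_checks["discrete_expected_full_complexes"] = (
                    state.expected_full_complexes)
            log("oracle: discrete expectation "
                f"{_fmt(oracle_checks['discrete_expected_full_complexes'])} vs "
                f"analytic {_fmt(analytic_at_s)}")
        else:
            log("oracle: discrete check skipped (non-integer counts or above "
                "enumeration guard)")

    summary = {
        "scenario": scenario.to_dict(),
        "seed": seed,
        "full_complex_max": float(curve.full_complex.max()),
        "optimal_range": {
            "lower": rng.lower, "upper": rng.upper,
            "peak_value": rng.peak_value, "threshold": rng.threshold,
            "method": rng.method,
        },
        "oracle_checks": oracle_checks,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log("wrote: titration.csv optimal_range.csv summary.json")
    with open(outdir / "pipeline.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return summary


def preset_checksum() -> str:
    """SHA-256 over the canonical JSON of all presets (pins the presets)."""
    payload = json.dumps(
        {name: sc.to_dict() for name, sc in sorted(canonical_presets().items())},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()
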