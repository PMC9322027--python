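"""First-order acyl-migration/hydrolysis reaction networks.

An acyl group on a pyranoside hops between adjacent hydroxyl positions
(O2 <-> O3 <-> O4 [<-> O6]) and is irreversibly lost to hydrolysis.  With
every step first order, the species mole fractions c(t) obey the linear
system dc/dt = M c whose generator M is assembled from per-edge forward and
backward migration constants plus per-position hydrolysis constants.  The
hydrolyzed product is a single absorbing sink; re-acylation is not modeled.

Two standard topologies cover the experimental series:

* path A — four acylated positions, the last one a primary hydroxyl (O6),
  with a common secondary-hydrolysis constant and an optionally distinct
  primary-hydrolysis constant;
* path B — three secondary positions (pentopyranosides, deoxyhexoses) with
  a single hydrolysis constant.

All rate constants in this module are in h^-1; conversion to s^-1 lives in
:mod:`acylmig.mechanism`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg

from .errors import ConfigurationError, NonEquilibratingError, ValidationError

__all__ = [
    "MigrationScheme",
    "RateSet",
    "TimeCourse",
    "path_a",
    "path_b",
    "build_rate_matrix",
    "simulate",
    "equilibrium_ratios",
    "equilibrium_composition",
    "time_to_equilibrium",
]

_HYDROLYSIS_CLASSES = ("secondary", "primary", "none")

#: Tolerance on the row sums of simulated fraction trajectories.
MASS_TOL = 1e-9


@dataclass(frozen=True)
class MigrationScheme:
    """Topology of a migration network.

    Parameters
    ----------
    positions:
        Ordered acyl-position labels along the migration path, e.g.
        ``("O2", "O3", "O4", "O6")``.  Migration edges connect consecutive
        positions only (the hydroxyls must be adjacent in space; no
        O2->O6 shortcut).
    hydrolysis:
        Hydrolysis class per position: ``"secondary"``, ``"primary"`` or
        ``"none"``.
    sink:
        Label of the absorbing deacylated product.
    start:
        Position initially carrying the acyl group (default: first).
    """

    positions: tuple[str, ...]
    hydrolysis: tuple[str, ...]
    sink: str = "hydrolyzed"
    start: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", tuple(self.positions))
        object.__setattr__(self, "hydrolysis", tuple(self.hydrolysis))
        if len(self.positions) < 2:
            raise ConfigurationError("a migration scheme needs >= 2 positions")
        if len(set(self.positions)) != len(self.positions):
            raise ConfigurationError("duplicate position labels")
        if len(self.hydrolysis) != len(self.positions):
            raise ConfigurationError(
                "hydrolysis classes must match positions one-to-one"
            )
        for cls in self.hydrolysis:
            if cls not in _HYDROLYSIS_CLASSES:
                raise ConfigurationError(f"unknown hydrolysis class {cls!r}")
        if self.sink in self.positions:
            raise ConfigurationError("sink label collides with a position")
        if self.start is None:
            object.__setattr__(self, "start", self.positions[0])
        elif self.start not in self.positions:
            raise ConfigurationError(f"start {self.start!r} not a position")

    @property
    def n_edges(self) -> int:
        return len(self.positions) - 1

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(self.positions[:-1], self.positions[1:]))

    @property
    def species(self) -> tuple[str, ...]:
        """All species in column order: positions along the path, sink last."""
        return self.positions + (self.sink,)

    @property
    def has_hydrolysis(self) -> bool:
        return any(cls != "none" for cls in self.hydrolysis)

    def without_hydrolysis(self) -> "MigrationScheme":
        return replace(self, hydrolysis=("none",) * len(self.positions))


def path_a(
    positions: Sequence[str] = ("O2", "O3", "O4", "O6"),
    start: str | None = None,
) -> MigrationScheme:
    """Four-position scheme ending in a primary hydroxyl (hexopyranosides)."""
    positions = tuple(positions)
    if len(positions) != 4:
        raise ConfigurationError("path A has exactly 4 positions")
    return MigrationScheme(
        positions=positions,
        hydrolysis=("secondary",) * 3 + ("primary",),
        start=start,
    )


def path_b(
    positions: Sequence[str] = ("O2", "O3", "O4"),
    start: str | None = None,
    hydrolysis: bool = True,
) -> MigrationScheme:
    """Three-secondary-position scheme (pentopyranosides, Rha, Fuc).

    ``hydrolysis=False`` drops the hydrolysis channel entirely, as used for
    ribopyranosides where the hydrolysis constant was not determined.
    """
    positions = tuple(positions)
    if len(positions) != 3:
        raise ConfigurationError("path B has exactly 3 positions")
    cls = "secondary" if hydrolysis else "none"
    return MigrationScheme(
        positions=positions, hydrolysis=(cls,) * 3, start=start
    )


@dataclass(frozen=True)
class RateSet:
    """Rate constants (h^-1) for one scheme.

    ``k_fwd[i]``/``k_bwd[i]`` are the forward/backward migration constants of
    edge *i* (positions i -> i+1).  ``k_hyd_secondary`` is the common
    hydrolysis constant of every secondary position; ``k_hyd_primary``, when
    given, differentiates hydrolysis from the primary position (otherwise the
    primary position uses the secondary constant — the equal-hydrolysis
    assumption).
    """

    k_fwd: tuple[float, ...]
    k_bwd: tuple[float, ...]
    k_hyd_secondary: float = 0.0
    k_hyd_primary: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "k_fwd", tuple(float(k) for k in self.k_fwd))
        object.__setattr__(self, "k_bwd", tuple(float(k) for k in self.k_bwd))
        if len(self.k_fwd) != len(self.k_bwd):
            raise ConfigurationError("k_fwd and k_bwd must have equal length")
        for k in (*self.k_fwd, *self.k_bwd, self.k_hyd_secondary):
            if not np.isfinite(k) or k < 0:
                raise ValidationError(f"rate constants must be >= 0, got {k}")
        if self.k_hyd_primary is not None:
            kp = float(self.k_hyd_primary)
            if not np.isfinite(kp) or kp < 0:
                raise ValidationError(f"rate constants must be >= 0, got {kp}")
            object.__setattr__(self, "k_hyd_primary", kp)

    @property
    def n_edges(self) -> int:
        return len(self.k_fwd)

    def hydrolysis_constant(self, cls: str) -> float:
        if cls == "none":
            return 0.0
        if cls == "secondary":
            return self.k_hyd_secondary
        if cls == "primary":
            if self.k_hyd_primary is None:
                return self.k_hyd_secondary
            return self.k_hyd_primary
        raise ConfigurationError(f"unknown hydrolysis class {cls!r}")

    def scaled(self, coefficient: float) -> "RateSet":
        """All constants multiplied by one condition coefficient."""
        if coefficient <= 0:
            raise ValidationError("condition coefficient must be > 0")
        return RateSet(
            k_fwd=tuple(coefficient * k for k in self.k_fwd),
            k_bwd=tuple(coefficient * k for k in self.k_bwd),
            k_hyd_secondary=coefficient * self.k_hyd_secondary,
            k_hyd_primary=(
                None
                if self.k_hyd_primary is None
                else coefficient * self.k_hyd_primary
            ),
        )


@dataclass
class TimeCourse:
    """Sampled species fractions over time.

    ``fractions[t, s]`` is the mole fraction of species ``species[s]`` at
    ``times[t]`` (hours).  Simulated data sums to 1 per row to 1e-9;
    observed (noisy) data may violate the [0, 1] bounds by at most
    ``OBSERVED_TOL``.
    """

    times: np.ndarray
    fractions: np.ndarray
    species: tuple[str, ...]
    meta: dict = field(default_factory=dict)
    observed: bool = False
    bound_tol: float | None = None  # override of the [0, 1] slack

    OBSERVED_TOL = 0.05

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.species = tuple(self.species)
        if self.times.ndim != 1:
            raise ValidationError("times must be one-dimensional")
        if self.fractions.shape != (self.times.size, len(self.species)):
            raise ValidationError(
                f"fractions shape {self.fractions.shape} does not match "
                f"{self.times.size} times x {len(self.species)} species"
            )
        if self.times.size and self.times[0] < 0:
            raise ValidationError("times must be >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        tol = self.bound_tol
        if tol is None:
            tol = self.OBSERVED_TOL if self.observed else MASS_TOL
        if np.any(self.fractions < -tol) or np.any(self.fractions > 1 + tol):
            raise ValidationError(
                f"species fractions outside [0, 1] by more than {tol}"
            )

    @property
    def n_times(self) -> int:
        return self.times.size

    def column(self, species: str) -> np.ndarray:
        return self.fractions[:, self.species.index(species)]


def _rates_for_scheme(scheme: MigrationScheme, rates: RateSet) -> None:
    if rates.n_edges != scheme.n_edges:
        raise ConfigurationError(
            f"rate set has {rates.n_edges} edges, scheme needs {scheme.n_edges}"
        )


def build_rate_matrix(scheme: MigrationScheme, rates: RateSet) -> np.ndarray:
    """Generator matrix M of dc/dt = M c over ``scheme.species``.

    Entry ``M[j, i]`` is the first-order flow rate from species i to species
    j (h^-1); diagonals hold the negative total outflow so that every column
    sums to zero exactly (mass conservation, sink included).  The sink
    column is zero: the deacylated product is absorbing.
    """
    _rates_for_scheme(scheme, rates)
    n = len(scheme.species)
    m = np.zeros((n, n))
    for i, (kf, kb) in enumerate(zip(rates.k_fwd, rates.k_bwd)):
        m[i + 1, i] += kf
        m[i, i + 1] += kb
    sink = n - 1
    for i, cls in enumerate(scheme.hydrolysis):
        m[sink, i] += rates.hydrolysis_constant(cls)
    np.fill_diagonal(m, 0.0)
    np.fill_diagonal(m, -m.sum(axis=0))
    return m


def _initial_vector(
    scheme: MigrationScheme,
    initial: Mapping[str, float] | Sequence[float] | None,
) -> np.ndarray:
    species = scheme.species
    if initial is None:
        c0 = np.zeros(len(species))
        c0[species.index(scheme.start)] = 1.0
        return c0
    if isinstance(initial, Mapping):
        c0 = np.array([float(initial.get(s, 0.0)) for s in species])
    else:
        c0 = np.asarray(initial, dtype=float)
        if c0.shape != (len(species),):
            raise ValidationError(
                f"initial vector needs {len(species)} entries (sink last)"
            )
    if np.any(c0 < 0):
        raise ValidationError("initial fractions must be >= 0")
    if abs(c0.sum() - 1.0) > 1e-8:
        raise ValidationError("initial fractions must sum to 1")
    return c0


def _propagate(m: np.ndarray, c0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Exact solution of dc/dt = M c at the given times.

    Eigendecomposition when M is safely diagonalizable; otherwise a
    scaling-and-squaring matrix exponential per time point (handles
    defective/degenerate generators at the same accuracy).
    """
    traj = None
    try:
        vals, vecs = np.linalg.eig(m)
        cond = np.linalg.cond(vecs)
    except np.linalg.LinAlgError:  # pragma: no cover - eig rarely fails
        cond = np.inf
    if np.isfinite(cond) and cond < 1e8:
        a = np.linalg.solve(vecs, c0.astype(complex))
        traj = np.ascontiguousarray(
            ((np.exp(np.outer(times, vals)) * a) @ vecs.T).real
        )
        ok = (
            np.all(traj > -MASS_TOL)
            and np.all(traj < 1 + MASS_TOL)
            and np.all(np.abs(traj.sum(axis=1) - c0.sum()) < MASS_TOL)
        )
        if not ok:
            traj = None
    if traj is None:
        # defective or ill-conditioned eigenbasis (or visible roundoff):
        # scaling-and-squaring matrix exponential, backward stable
        traj = np.empty((times.size, c0.size))
        for i, t in enumerate(times):
            traj[i] = scipy.linalg.expm(m * t) @ c0
    # the analytic solution lives in [0, 1]; clip sub-roundoff excursions
    # (O(1e-8) at worst for extreme ||M t||) back onto the physical range
    np.clip(traj, 0.0, 1.0, out=traj)
    return traj


def simulate(
    scheme: MigrationScheme,
    rates: RateSet,
    times: Sequence[float] | np.ndarray,
    initial: Mapping[str, float] | Sequence[float] | None = None,
) -> TimeCourse:
    """Exact species-fraction trajectory of the linear migration network.

    ``initial`` defaults to a pure starting isomer (fraction 1 at
    ``scheme.start``).  Rows of the result sum to 1 within 1e-9.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValidationError("times must be a non-empty 1-D sequence")
    if times[0] < 0:
        raise ValidationError("times must be >= 0")
    if np.any(np.diff(times) <= 0):
        raise ValidationError("times must be strictly increasing")
    c0 = _initial_vector(scheme, initial)
    m = build_rate_matrix(scheme, rates)
    traj = _propagate(m, c0, times)
    meta = {"scheme": scheme.positions, "start": scheme.start}
    return TimeCourse(
        times=times, fractions=traj, species=scheme.species, meta=meta
    )


def equilibrium_ratios(rates: RateSet) -> np.ndarray:
    """Equilibrium abundance ratio across each migration edge.

    Hydrolysis is ignored: on the time scale of migration the network of
    acylated isomers pre-equilibrates (detailed balance on a chain), so the
    ratio of species i+1 to species i is simply k_fwd[i] / k_bwd[i].
    """
    k_bwd = np.asarray(rates.k_bwd)
    if np.any(k_bwd == 0):
        raise ValidationError(
            "equilibrium ratios undefined: a backward migration constant is "
            "zero, the chain drains irreversibly"
        )
    return np.asarray(rates.k_fwd) / k_bwd


def equilibrium_composition(rates: RateSet) -> np.ndarray:
    """Normalized equilibrium composition of the acylated isomers."""
    ratios = equilibrium_ratios(rates)
    comp = np.concatenate([[1.0], np.cumprod(ratios)])
    return comp / comp.sum()


def time_to_equilibrium(
    scheme: MigrationScheme,
    rates: RateSet,
    tolerance: float,
    initial: Mapping[str, float] | Sequence[float] | None = None,
    include_hydrolysis: bool = False,
    t_max: float = 1e5,
    n_grid: int = 4000,
) -> float:
    """Smallest simulated time at which the migration network is equilibrated.

    Every acylated-species fraction must lie within ``tolerance`` (absolute,
    in fraction units) of its equilibrium value.  By default hydrolysis
    constants are zeroed so the question is purely about the migration
    sub-network; with ``include_hydrolysis=True`` the instantaneous acylated
    composition is renormalized before comparison.
    """
    if not 0 < tolerance < 1:
        raise ValidationError("tolerance must be in (0, 1)")
    if any(k == 0 for k in rates.k_bwd):
        raise NonEquilibratingError(
            "all-forward chain never equilibrates (some k_bwd = 0)"
        )
    eq = equilibrium_composition(rates)
    sim_scheme = scheme if include_hydrolysis else scheme.without_hydrolysis()
    grid = np.concatenate([[0.0], np.geomspace(1e-4, t_max, n_grid)])
    tc = simulate(sim_scheme, rates, grid, initial=initial)
    acyl = tc.fractions[:, : len(scheme.positions)]
    if include_hydrolysis:
        tot = acyl.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        acyl = acyl / tot
    dev = np.abs(acyl - eq).max(axis=1)
    ok = dev <= tolerance
    # first time after which the criterion holds for good
    idx = np.nonzero(~ok)[0]
    if ok[-1] and idx.size == 0:
        return float(grid[0])
    if not ok[-1]:
        raise NonEquilibratingError(
            f"not equilibrated to {tolerance} within {t_max} h"
        )
    first = idx[-1] + 1
    lo, hi = grid[first - 1], grid[first]
    # bisect the crossing for a grid-independent answer
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        c = simulate(sim_scheme, rates, [mid], initial=initial).fractions[0]
        a = c[: len(scheme.positions)]
        if include_hydrolysis:
            s = a.sum()
            a = a / (s if s else 1.0)
        if np.abs(a - eq).max() <= tolerance:
            hi = mid
        else:
            lo = mid
    return float(hi)
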