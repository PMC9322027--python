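"""Rate-constant estimation from species-fraction time courses.

The forward model is the exact linear-network simulation of
:mod:`acylmig.network`; parameters are estimated by bounded trust-region
nonlinear least squares on the unweighted fraction residuals, restarted from
a seeded log-uniform grid so the reported optimum is the best of several
starts.  Standard errors come from the linearized covariance
sigma^2 (J^T J)^-1 at the optimum.

A single uniform condition coefficient (buffer strength, pH) can likewise
be fitted by scaling a fixed reference rate set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import ConfigurationError, ValidationError
from .network import MigrationScheme, RateSet, TimeCourse, simulate

__all__ = [
    "FitResult",
    "ConditionCoefficient",
    "param_names",
    "fit_rates",
    "fit_condition_coefficient",
]

_START_LOW, _START_HIGH = 1e-4, 10.0  # h^-1, log-uniform multi-start window


def param_names(
    scheme: MigrationScheme, separate_primary: bool = False
) -> list[str]:
    """Free-parameter labels in the conventional numbering.

    Edge constants come first (k1, k-1, k2, k-2, ...), then the common
    hydrolysis constant, then — when the primary position is differentiated —
    its separate constant.  Path A: k1..k-3, k4 (, k5); path B: k1..k-2, k3.
    """
    names: list[str] = []
    for i in range(1, scheme.n_edges + 1):
        names += [f"k{i}", f"k-{i}"]
    if scheme.has_hydrolysis:
        names.append(f"k{scheme.n_edges + 1}")
        if separate_primary:
            if "primary" not in scheme.hydrolysis:
                raise ConfigurationError(
                    "scheme has no primary position to differentiate"
                )
            names.append(f"k{scheme.n_edges + 2}")
    return names


def _unpack(
    x: np.ndarray, scheme: MigrationScheme, separate_primary: bool
) -> RateSet:
    ne = scheme.n_edges
    kf = tuple(x[0 : 2 * ne : 2])
    kb = tuple(x[1 : 2 * ne : 2])
    i = 2 * ne
    k_sec = 0.0
    k_pri = None
    if scheme.has_hydrolysis:
        k_sec = x[i]
        i += 1
        if separate_primary:
            k_pri = x[i]
    return RateSet(
        k_fwd=kf, k_bwd=kb, k_hyd_secondary=k_sec, k_hyd_primary=k_pri
    )


def _pack(rates: RateSet, scheme: MigrationScheme, separate_primary: bool):
    x: list[float] = []
    for kf, kb in zip(rates.k_fwd, rates.k_bwd):
        x += [kf, kb]
    if scheme.has_hydrolysis:
        x.append(rates.k_hyd_secondary)
        if separate_primary:
            x.append(
                rates.k_hyd_secondary
                if rates.k_hyd_primary is None
                else rates.k_hyd_primary
            )
    return np.array(x)


@dataclass
class FitResult:
    """Outcome of a rate-constant fit."""

    scheme: MigrationScheme
    estimates: RateSet
    param_names: list[str]
    values: np.ndarray  # same order as param_names
    standard_errors: np.ndarray  # NaN where unavailable
    covariance: np.ndarray | None
    residual_norm: float  # sqrt(sum of squared residuals)
    n_data: int
    converged: bool
    identifiable: bool
    bound_hits: np.ndarray  # bool per parameter, estimate pinned at 0
    n_starts: int
    start_costs: np.ndarray  # best cost reached from each start

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {
            name: (float(v), float(se))
            for name, v, se in zip(
                self.param_names, self.values, self.standard_errors
            )
        }


def _as_timecourses(data) -> list[TimeCourse]:
    if isinstance(data, TimeCourse):
        return [data]
    courses = list(data)
    if not courses or not all(isinstance(tc, TimeCourse) for tc in courses):
        raise ValidationError("data must be a TimeCourse or a list of them")
    return courses


def _check_columns(scheme: MigrationScheme, courses: list[TimeCourse]) -> None:
    for tc in courses:
        if tuple(tc.species) != scheme.species:
            raise ConfigurationError(
                f"time-course species {tc.species} do not match scheme "
                f"species {scheme.species}"
            )


def fit_rates(
    data: TimeCourse | Sequence[TimeCourse],
    scheme: MigrationScheme,
    separate_primary: bool = False,
    n_starts: int = 5,
    seed: int = 0,
    initial: Mapping[str, float] | Sequence[float] | None = None,
    x0: RateSet | None = None,
    max_nfev: int | None = None,
) -> FitResult:
    """Estimate all scheme rate constants from one or more time courses.

    Parameters
    ----------
    data:
        Observed time course(s); species columns must match the scheme.
    separate_primary:
        Fit a distinct hydrolysis constant for the primary position
        (otherwise all positions share one constant).
    n_starts:
        Number of optimizer starts; the first is a fixed heuristic, the rest
        are seeded log-uniform draws in [1e-4, 10] h^-1.
    initial:
        Initial species-fraction vector for the forward model
        (default: pure starting isomer of the scheme).
    x0:
        Optional user-supplied first start.
    """
    courses = _as_timecourses(data)
    _check_columns(scheme, courses)
    names = param_names(scheme, separate_primary)
    n_par = len(names)
    n_data = sum(tc.fractions.size for tc in courses)
    if n_data < 3 * n_par:
        raise ValidationError(
            f"need >= {3 * n_par} data values for {n_par} parameters, "
            f"got {n_data}"
        )

    def residuals(x: np.ndarray) -> np.ndarray:
        rates = _unpack(x, scheme, separate_primary)
        out = []
        for tc in courses:
            sim = simulate(scheme, rates, tc.times, initial=initial)
            out.append((sim.fractions - tc.fractions).ravel())
        return np.concatenate(out)

    rng = np.random.default_rng(seed)
    starts = []
    if x0 is not None:
        starts.append(_pack(x0, scheme, separate_primary))
    else:
        heuristic = np.full(n_par, 0.1)
        if scheme.has_hydrolysis:
            heuristic[2 * scheme.n_edges :] = 0.01
        starts.append(heuristic)
    while len(starts) < n_starts:
        starts.append(
            np.exp(
                rng.uniform(
                    np.log(_START_LOW), np.log(_START_HIGH), size=n_par
                )
            )
        )

    best = None
    start_costs = []
    for s in starts:
        res = least_squares(
            residuals,
            s,
            bounds=(0.0, np.inf),
            method="trf",
            x_scale="jac",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=max_nfev,
        )
        start_costs.append(res.cost)
        if best is None or res.cost < best.cost:
            best = res

    x = best.x
    jac = best.jac
    dof = max(n_data - n_par, 1)
    sigma2 = 2.0 * best.cost / dof
    jtj = jac.T @ jac
    identifiable = (
        np.all(np.isfinite(jtj)) and np.linalg.cond(jtj) < 1e12
    )
    if identifiable:
        cov = sigma2 * np.linalg.inv(jtj)
        stderr = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    else:
        cov = None
        stderr = np.full(n_par, np.nan)

    return FitResult(
        scheme=scheme,
        estimates=_unpack(x, scheme, separate_primary),
        param_names=names,
        values=x.copy(),
        standard_errors=stderr,
        covariance=cov,
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        n_data=n_data,
        converged=bool(best.status > 0),
        identifiable=bool(identifiable),
        bound_hits=x <= 1e-12,
        n_starts=len(starts),
        start_costs=np.array(start_costs),
    )


@dataclass
class ConditionCoefficient:
    """Uniform multiplier mapping reference rates onto another condition."""

    coefficient: float
    stderr: float
    residual_rms: float
    consistent: bool  # False if residuals exceed the uniform-scaling threshold
    reference: RateSet
    condition: dict

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValidationError("condition coefficient must be > 0")


def fit_condition_coefficient(
    reference_rates: RateSet,
    data: TimeCourse,
    scheme: MigrationScheme,
    initial: Mapping[str, float] | Sequence[float] | None = None,
    residual_threshold: float = 0.05,
) -> ConditionCoefficient:
    """One scalar c minimizing || simulate(c * reference) - data ||.

    A root-mean-square residual above ``residual_threshold`` flags the data
    as inconsistent with uniform scaling of all constants.
    """
    _check_columns(scheme, [data])

    def residuals(logc: np.ndarray) -> np.ndarray:
        rates = reference_rates.scaled(float(np.exp(logc[0])))
        sim = simulate(scheme, rates, data.times, initial=initial)
        return (sim.fractions - data.fractions).ravel()

    best = None
    for c0 in (1.0, 0.01, 100.0):
        res = least_squares(
            residuals,
            np.array([np.log(c0)]),
            method="lm",
            xtol=1e-15,
            ftol=1e-15,
        )
        if best is None or res.cost < best.cost:
            best = res
    c = float(np.exp(best.x[0]))
    n = data.fractions.size
    rms = float(np.sqrt(2.0 * best.cost / n))
    dof = max(n - 1, 1)
    sigma2 = 2.0 * best.cost / dof
    jtj = float(np.sum(best.jac**2))
    # delta method: fit is in log c, stderr transformed back to c
    stderr_logc = np.sqrt(sigma2 / jtj) if jtj > 0 else np.nan
    return ConditionCoefficient(
        coefficient=c,
        stderr=float(c * stderr_logc),
        residual_rms=rms,
        consistent=bool(rms <= residual_threshold),
        reference=reference_rates,
        condition=dict(data.meta),
    )
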