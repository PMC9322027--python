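"""Transition-state-theory rate algebra for the migration mechanism.

Each migration step proceeds through a cyclic orthoester intermediate and
can run on two parallel tracks: a neutral, water-mediated track starting
from the protonated hydroxyl, and an anionic track starting from the
deprotonated hydroxyl.  The anion is only available in proportion to
Keq/[H+] with Keq = 10^(-pKa) of the attacking hydroxyl, so the observed
first-order constant for one direction of one step is

    k_obs = k_neutral + k_anionic * Keq / [H+]

with both contributions non-negative.  Each two-step track collapses to a
single composite constant via the steady-state treatment of the orthoester,

    k_composite_fwd = k_a * k_b / (k_-a + k_b)
    k_composite_rev = k_-a * k_-b / (k_-a + k_b)

and every rate constant interconverts with a formal free-energy barrier
through the Eyring equation k = kappa * (kB*T/h) * exp(-dG/RT).

Rate constants in this module are in s^-1 and barriers in kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import UnitError, ValidationError

__all__ = [
    "KB",
    "PLANCK_H",
    "R_KCAL",
    "Conditions",
    "StepRates",
    "MigrationStep",
    "MechanismSpec",
    "ObservedRatePrediction",
    "EnergyProfile",
    "eyring_barrier_from_rate",
    "eyring_rate_from_barrier",
    "keq_from_pka",
    "composite_rate",
    "observed_rate",
    "ph_coefficient",
    "convert_rate_units",
    "energy_profile_from_kobs",
]

# CODATA 2018
KB = 1.380649e-23  # J/K
PLANCK_H = 6.62607015e-34  # J*s
R_KCAL = 1.98720425e-3  # kcal/(mol*K)

SECONDS_PER_HOUR = 3600.0

_UNIT_ALIASES = {
    "h^-1": "h^-1",
    "1/h": "h^-1",
    "per_hour": "h^-1",
    "h-1": "h^-1",
    "s^-1": "s^-1",
    "1/s": "s^-1",
    "per_second": "s^-1",
    "s-1": "s^-1",
}


@dataclass(frozen=True)
class Conditions:
    """Medium and thermodynamic conditions.

    temperature in K, pH dimensionless, ``kw`` the water ion product and
    ``kappa`` the transmission coefficient of the Eyring prefactor.
    """

    temperature: float = 298.15
    pH: float = 8.0
    kw: float = 1e-14
    kappa: float = 1.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValidationError("temperature must be > 0 K")
        if not 0 <= self.pH <= 14:
            raise ValidationError("pH must lie in [0, 14]")
        if not 0 < self.kappa <= 1:
            raise ValidationError("kappa must lie in (0, 1]")

    @property
    def h_plus(self) -> float:
        """[H+] = 10^(-pH), activity coefficients ignored."""
        return 10.0 ** (-self.pH)

    @property
    def oh_minus(self) -> float:
        return self.kw / self.h_plus

    @property
    def rt(self) -> float:
        """RT in kcal/mol."""
        return R_KCAL * self.temperature

    @property
    def prefactor(self) -> float:
        """kappa * kB * T / h in s^-1 (~6.21e12 at 298.15 K, kappa 1)."""
        return self.kappa * KB * self.temperature / PLANCK_H


def eyring_barrier_from_rate(
    k: float, conditions: Conditions = Conditions()
) -> float:
    """Formal free-energy barrier (kcal/mol) of a first-order rate (s^-1)."""
    k = np.asarray(k, dtype=float)
    if np.any(k <= 0):
        raise ValidationError("Eyring conversion needs a rate > 0")
    out = -conditions.rt * np.log(k / conditions.prefactor)
    return float(out) if out.ndim == 0 else out


def eyring_rate_from_barrier(
    barrier: float, conditions: Conditions = Conditions()
) -> float:
    """Inverse of :func:`eyring_barrier_from_rate` (round trip ~1e-15)."""
    barrier = np.asarray(barrier, dtype=float)
    if not np.all(np.isfinite(barrier)):
        raise ValidationError("barrier must be finite")
    with np.errstate(over="raise"):
        out = conditions.prefactor * np.exp(-barrier / conditions.rt)
    return float(out) if out.ndim == 0 else out


def keq_from_pka(pka: float) -> float:
    """Acid-dissociation constant of the attacking hydroxyl: 10^(-pKa)."""
    if not math.isfinite(pka):
        raise ValidationError("pKa must be finite")
    return 10.0 ** (-pka)


@dataclass(frozen=True)
class StepRates:
    """Elementary constants of one two-step migration track (s^-1).

    ``ka``/``k_minus_a`` form and revert the orthoester, ``kb``/``k_minus_b``
    collapse it to product and revert.  Construct from free-energy barriers
    of the individual steps with :meth:`from_barriers`.
    """

    ka: float
    k_minus_a: float
    kb: float
    k_minus_b: float

    def __post_init__(self) -> None:
        for k in (self.ka, self.k_minus_a, self.kb, self.k_minus_b):
            if not (math.isfinite(k) and k > 0):
                raise ValidationError("elementary rates must be > 0")

    @classmethod
    def from_barriers(
        cls,
        dg_a: float,
        dg_minus_a: float,
        dg_b: float,
        dg_minus_b: float,
        conditions: Conditions = Conditions(),
    ) -> "StepRates":
        return cls(
            ka=eyring_rate_from_barrier(dg_a, conditions),
            k_minus_a=eyring_rate_from_barrier(dg_minus_a, conditions),
            kb=eyring_rate_from_barrier(dg_b, conditions),
            k_minus_b=eyring_rate_from_barrier(dg_minus_b, conditions),
        )

    def barriers(
        self, conditions: Conditions = Conditions()
    ) -> tuple[float, float, float, float]:
        return tuple(
            eyring_barrier_from_rate(k, conditions)
            for k in (self.ka, self.k_minus_a, self.kb, self.k_minus_b)
        )


def composite_rate(steps: StepRates) -> tuple[float, float]:
    """Steady-state composite constants (forward, reverse) of a track.

    forward = ka*kb/(k_-a + kb); reverse = k_-a*k_-b/(k_-a + kb).  Both
    directions share the denominator of the orthoester steady state.
    """
    den = steps.k_minus_a + steps.kb
    if den == 0:
        raise ValidationError("zero denominator in composite rate")
    return steps.ka * steps.kb / den, steps.k_minus_a * steps.k_minus_b / den


@dataclass(frozen=True)
class ObservedRatePrediction:
    """One direction of one step: k_obs and its mechanistic decomposition."""

    k_obs: float
    neutral_term: float
    anionic_term: float
    barrier: float  # formal barrier of k_obs, kcal/mol
    conditions: Conditions

    @property
    def anionic_fraction(self) -> float:
        return self.anionic_term / self.k_obs


def observed_rate(
    neutral_composite: float,
    anionic_composite: float,
    keq: float,
    conditions: Conditions = Conditions(),
    anionic_only: bool = False,
) -> ObservedRatePrediction:
    """pH-dependent observed constant combining both mechanistic tracks.

    ``k_obs = k_neutral + k_anionic * Keq/[H+]``; with ``anionic_only=True``
    the (usually negligible) neutral term is dropped, giving the simplified
    anionic-mechanism expression.
    """
    if neutral_composite < 0 or anionic_composite < 0 or keq <= 0:
        raise ValidationError("rate terms must be >= 0 and Keq > 0")
    anionic_term = anionic_composite * keq / conditions.h_plus
    neutral_term = 0.0 if anionic_only else float(neutral_composite)
    k_obs = neutral_term + anionic_term
    return ObservedRatePrediction(
        k_obs=k_obs,
        neutral_term=neutral_term,
        anionic_term=anionic_term,
        barrier=eyring_barrier_from_rate(k_obs, conditions),
        conditions=conditions,
    )


def ph_coefficient(ph: float, reference_ph: float = 8.0) -> float:
    """[OH-] ratio between a pH and the reference pH: 10^(pH - ref)."""
    for p in (ph, reference_ph):
        if not 0 <= p <= 14:
            raise ValidationError("pH must lie in [0, 14]")
    return 10.0 ** (ph - reference_ph)


def convert_rate_units(k: float, from_unit: str, to_unit: str) -> float:
    """Convert a first-order rate constant between h^-1 and s^-1."""
    try:
        src = _UNIT_ALIASES[from_unit]
        dst = _UNIT_ALIASES[to_unit]
    except KeyError as exc:
        raise UnitError(f"unknown rate unit {exc.args[0]!r}") from None
    if src == dst:
        return float(k)
    if (src, dst) == ("h^-1", "s^-1"):
        return float(k) / SECONDS_PER_HOUR
    return float(k) * SECONDS_PER_HOUR


@dataclass(frozen=True)
class EnergyProfile:
    """Alternating minima and formal-barrier maxima along the migration path.

    ``minima[i]`` is the free energy (kcal/mol, first species = 0) of the
    i-th acylated isomer; ``maxima[i]`` the formal barrier top between
    isomers i and i+1.
    """

    minima: tuple[float, ...]
    maxima: tuple[float, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.maxima) != len(self.minima) - 1:
            raise ValidationError("need one maximum between consecutive minima")

    def interleaved(self) -> list[tuple[str, float]]:
        """(kind, energy) pairs in path order, for plotting or CSV export."""
        out: list[tuple[str, float]] = [("minimum", self.minima[0])]
        for mx, mn in zip(self.maxima, self.minima[1:]):
            out.append(("maximum", mx))
            out.append(("minimum", mn))
        return out


def energy_profile_from_kobs(
    pairs: Sequence[tuple[float, float]],
    conditions: Conditions = Conditions(),
    labels: Sequence[str] = (),
) -> EnergyProfile:
    """Reaction free-energy profile from observed rate-constant pairs.

    For each step (k_fwd_obs, k_bwd_obs) in path order: the next minimum
    lies RT*ln(k_bwd/k_fwd) above the previous one (thermodynamics of the
    step) and the intervening maximum sits one formal Eyring barrier of
    k_fwd_obs above the preceding minimum.
    """
    if not pairs:
        raise ValidationError("need at least one (k_fwd, k_bwd) pair")
    minima = [0.0]
    maxima = []
    rt = conditions.rt
    for kf, kb in pairs:
        if kf <= 0 or kb <= 0:
            raise ValidationError("observed rates must be > 0")
        maxima.append(minima[-1] + eyring_barrier_from_rate(kf, conditions))
        minima.append(minima[-1] + rt * math.log(kb / kf))
    return EnergyProfile(
        minima=tuple(minima), maxima=tuple(maxima), labels=tuple(labels)
    )


@dataclass(frozen=True)
class MigrationStep:
    """One migration step with both mechanistic tracks.

    ``pka_fwd`` is the pKa of the attacking hydroxyl on the protonated educt
    of the forward direction; ``pka_bwd`` the analogue for the reverse
    direction.  ``neutral`` and ``anionic`` are either :class:`StepRates`
    (elementary constants) or a ``(forward, reverse)`` composite pair.
    """

    label: str
    pka_fwd: float
    pka_bwd: float
    neutral: StepRates | tuple[float, float]
    anionic: StepRates | tuple[float, float]

    def __post_init__(self) -> None:
        for pka in (self.pka_fwd, self.pka_bwd):
            if not 0 <= pka <= 20:
                raise ValidationError("pKa must lie in [0, 20]")

    @staticmethod
    def _composites(track: StepRates | tuple[float, float]) -> tuple[float, float]:
        if isinstance(track, StepRates):
            return composite_rate(track)
        fwd, rev = track
        if fwd <= 0 or rev <= 0:
            raise ValidationError("composite constants must be > 0")
        return float(fwd), float(rev)

    @property
    def neutral_composites(self) -> tuple[float, float]:
        return self._composites(self.neutral)

    @property
    def anionic_composites(self) -> tuple[float, float]:
        return self._composites(self.anionic)

    def observed(
        self, conditions: Conditions, anionic_only: bool = False
    ) -> tuple[ObservedRatePrediction, ObservedRatePrediction]:
        nf, nr = self.neutral_composites
        af, ar = self.anionic_composites
        fwd = observed_rate(
            nf, af, keq_from_pka(self.pka_fwd), conditions, anionic_only
        )
        bwd = observed_rate(
            nr, ar, keq_from_pka(self.pka_bwd), conditions, anionic_only
        )
        return fwd, bwd


@dataclass(frozen=True)
class MechanismSpec:
    """Full mechanistic description of a migration path."""

    steps: tuple[MigrationStep, ...]
    conditions: Conditions = field(default_factory=Conditions)

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", tuple(self.steps))
        if not self.steps:
            raise ValidationError("a mechanism needs >= 1 step")

    def observed(
        self, anionic_only: bool = False
    ) -> list[tuple[ObservedRatePrediction, ObservedRatePrediction]]:
        return [s.observed(self.conditions, anionic_only) for s in self.steps]

    def energy_profile(self, anionic_only: bool = False) -> EnergyProfile:
        pairs = [
            (fwd.k_obs, bwd.k_obs) for fwd, bwd in self.observed(anionic_only)
        ]
        return energy_profile_from_kobs(
            pairs, self.conditions, labels=tuple(s.label for s in self.steps)
        )
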