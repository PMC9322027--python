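"""Synthetic NMR-like time courses with known ground truth.

Emulates integral-level species fractions from water-suppressed 1H NMR
monitoring of acyl migration: the exact network trajectory plus small
additive Gaussian noise on each fraction, truncated at zero.  Fractions are
NOT renormalized after adding noise — experimentally each species integral
is referenced independently to the OMe internal standard, so per-row sums
of observed data need not be exactly 1.

The default sampling design is 40 log-spaced points from 0.1 h to five
times the slowest relaxation time of the network, mirroring monitoring
campaigns that run from the first minutes out to a week or more for slow
migrations.  The default noise level sigma = 0.01 (one percent of the total
integral) is a modeling choice; the experimental error is only known to
grow when fast migration forces fewer scans per spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .network import MigrationScheme, RateSet, TimeCourse, build_rate_matrix, simulate

__all__ = ["SynthDesign", "default_times", "generate_timecourse", "generate_condition_series"]

DEFAULT_SIGMA = 0.01
DEFAULT_N_POINTS = 40


def default_times(
    scheme: MigrationScheme,
    rates: RateSet,
    n_points: int = DEFAULT_N_POINTS,
    t_min: float = 0.1,
) -> np.ndarray:
    """Log-spaced sampling grid out to 5x the slowest relaxation time."""
    m = build_rate_matrix(scheme, rates)
    vals = np.linalg.eigvals(m)
    decay = np.abs(vals.real)
    decay = decay[decay > 1e-12]
    tau = 1.0 / decay.min() if decay.size else 100.0
    t_max = max(5.0 * tau, 10.0 * t_min)
    return np.geomspace(t_min, t_max, n_points)


@dataclass(frozen=True)
class SynthDesign:
    """Recipe for one synthetic migration experiment.

    ``times=None`` selects the default log-spaced design for the (scaled)
    rates.  ``scale`` applies a uniform condition coefficient to all rate
    constants before simulating (buffer strength / pH analogue).  A seed is
    mandatory whenever sigma > 0.
    """

    scheme: MigrationScheme
    rates: RateSet
    times: np.ndarray | None = None
    sigma: float = DEFAULT_SIGMA
    detection_threshold: float = 0.0
    seed: int | None = None
    scale: float = 1.0
    initial: Mapping[str, float] | Sequence[float] | None = None
    conditions: dict = field(
        default_factory=lambda: {
            "pH": 8.0,
            "buffer_mM": 100.0,
            "temperature_K": 298.15,
        }
    )

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if self.sigma > 0 and self.seed is None:
            raise ValidationError("a seed is mandatory when sigma > 0")
        if self.detection_threshold < 0:
            raise ValidationError("detection threshold must be >= 0")
        if self.scale <= 0:
            raise ValidationError("scale must be > 0")
        if self.times is not None:
            t = np.asarray(self.times, dtype=float)
            if t.ndim != 1 or np.any(np.diff(t) <= 0):
                raise ValidationError("times must be strictly increasing")
            object.__setattr__(self, "times", t)

    def effective_rates(self) -> RateSet:
        return self.rates if self.scale == 1.0 else self.rates.scaled(self.scale)

    def sampling_times(self) -> np.ndarray:
        if self.times is not None:
            return self.times
        return default_times(self.scheme, self.effective_rates())


def generate_timecourse(design: SynthDesign) -> tuple[TimeCourse, dict]:
    """Simulate one experiment; returns (time course, ground-truth record).

    With sigma = 0 the output equals :func:`acylmig.network.simulate`
    exactly.  The same seed always reproduces the same noise stream.
    """
    rates = design.effective_rates()
    times = design.sampling_times()
    clean = simulate(design.scheme, rates, times, initial=design.initial)
    fractions = clean.fractions
    if design.sigma > 0:
        rng = np.random.default_rng(design.seed)
        fractions = np.maximum(
            fractions + rng.normal(0.0, design.sigma, fractions.shape), 0.0
        )
    if design.detection_threshold > 0:
        fractions = np.where(
            fractions < design.detection_threshold, 0.0, fractions
        )
    meta = dict(design.conditions)
    meta.update(noisy=design.sigma > 0, sigma=design.sigma, scale=design.scale)
    tc = TimeCourse(
        times=times,
        fractions=fractions,
        species=design.scheme.species,
        meta=meta,
        observed=design.sigma > 0,
        # noise can push integrals past 1; allow the usual slack plus ~5 s.d.
        bound_tol=TimeCourse.OBSERVED_TOL + 5.0 * design.sigma,
    )
    truth = {
        "rates": rates,
        "base_rates": design.rates,
        "scale": design.scale,
        "sigma": design.sigma,
        "seed": design.seed,
        "times": times,
        "clean": clean,
    }
    return tc, truth


def generate_condition_series(
    design: SynthDesign, coefficients: Sequence[float]
) -> list[tuple[TimeCourse, dict]]:
    """One experiment per uniform rate multiplier, independently seeded.

    Each condition is simulated from coefficient * rates with its own noise
    stream spawned from the design seed.  With ``times=None`` the sampling
    window adapts to each scaled network, as an experimentalist would
    monitor a slower condition for longer.
    """
    coefficients = list(coefficients)
    if any(c <= 0 for c in coefficients):
        raise ValidationError("condition multipliers must be > 0")
    if design.sigma > 0:
        children = np.random.SeedSequence(design.seed).spawn(len(coefficients))
        seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    else:
        seeds = [design.seed] * len(coefficients)
    out = []
    for c, s in zip(coefficients, seeds):
        sub = replace(design, scale=design.scale * c, seed=s)
        tc, truth = generate_timecourse(sub)
        truth["coefficient"] = c
        out.append((tc, truth))
    return out
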