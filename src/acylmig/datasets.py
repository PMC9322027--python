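"""Curated published reference values used as fixtures and worked examples.

Experimental migration/hydrolysis rate constants (h^-1, pH 8, 25 C, 100 mM
phosphate buffer) for a few representative compounds, the computed pKa
values of the acetylated alpha-D-glucopyranoside hydroxyls, the composite
mechanistic constants (s^-1) of the neutral and anionic tracks, the observed
rate constants at pH 8, and the pH / buffer-strength condition coefficients.

These numbers are inputs to the package, not outputs: the underlying NMR
spectra and quantum-chemical calculations are outside its scope.
"""

from __future__ import annotations

from .mechanism import Conditions, MechanismSpec, MigrationStep
from .network import MigrationScheme, RateSet, path_a, path_b

__all__ = [
    "COMPOUND_RATES",
    "COMPOUND_STDERRS",
    "compound_scheme",
    "PKA_ALPHA_GLC",
    "NEUTRAL_COMPOSITES_ALPHA_GLC",
    "ANIONIC_COMPOSITES_ALPHA_GLC",
    "OBSERVED_ALPHA_GLC_EXPERIMENTAL",
    "OBSERVED_ALPHA_GLC_PREDICTED",
    "OBSERVED_BETA_GLC_EXPERIMENTAL",
    "PH_COEFFICIENTS",
    "BUFFER_COEFFICIENTS",
    "alpha_glc_mechanism",
]

# Experimental rate constants for representative compounds.
# 1  = Ac on Me alpha-D-glucopyranoside   (path A, start O2)
# 4  = (R)-2-Ph-propanoyl on Me alpha-D-Glc (path A, separate primary k5)
# 6  = Ac on Me beta-D-glucopyranoside    (path A, start O2)
# 21 = Ac on Me alpha-D-mannopyranoside   (path A, start O2)
# 36 = Ac on Me beta-D-ribopyranoside     (path B, hydrolysis not determined)
# 38 = Piv on Me beta-D-ribopyranoside    (path B, hydrolysis not determined)
COMPOUND_RATES: dict[int, RateSet] = {
    1: RateSet(
        k_fwd=(2.26e-1, 1.82e-1, 4.34e0),
        k_bwd=(1.84e-1, 3.64e-1, 2.82e-1),
        k_hyd_secondary=3.17e-3,
    ),
    4: RateSet(
        k_fwd=(5.64e-2, 3.22e-2, 3.75e-1),
        k_bwd=(6.44e-2, 1.38e-1, 6.86e-3),
        k_hyd_secondary=5.01e-3,
        k_hyd_primary=2.92e-4,
    ),
    6: RateSet(
        k_fwd=(7.28e-1, 4.14e-1, 3.95e0),
        k_bwd=(4.00e-1, 4.62e-1, 1.64e-1),
        k_hyd_secondary=2.66e-3,
    ),
    21: RateSet(
        k_fwd=(1.91e0, 1.41e-1, 1.69e0),
        k_bwd=(1.39e0, 5.63e-1, 7.48e-2),
        k_hyd_secondary=3.02e-3,
    ),
    36: RateSet(k_fwd=(3.04e1, 1.85e1), k_bwd=(1.13e1, 2.20e1)),
    38: RateSet(k_fwd=(3.62e-1, 1.92e-1), k_bwd=(1.05e-1, 3.27e-1)),
}

#: Reported standard errors for compound 1, same ordering as the RateSet.
COMPOUND_STDERRS: dict[int, dict[str, float]] = {
    1: {
        "k1": 7.14e-3,
        "k-1": 1.42e-2,
        "k2": 1.23e-2,
        "k-2": 1.09e-1,
        "k3": 2.20e0,
        "k-3": 1.79e-1,
        "k4": 2.70e-4,
    },
}

_PATH_B_NO_HYD = (36, 38)


def compound_scheme(compound: int) -> MigrationScheme:
    """Scheme used for a curated compound (path A vs path B topology)."""
    if compound in _PATH_B_NO_HYD:
        return path_b(hydrolysis=False)
    return path_a()


#: Computed pKa of the attacking hydroxyl on each protonated acetylated
#: alpha-D-glucopyranoside (O2-Ac and O3-Ac species).
PKA_ALPHA_GLC: dict[str, float] = {"2Ac": 12.9, "3Ac": 12.0}

#: Composite constants (s^-1, barrier kcal/mol) of the neutral,
#: one-water-mediated track for the three acetyl migration steps in
#: Me alpha-D-glucopyranoside: (O2->O3, O3->O4, O4->O6) forward/reverse.
NEUTRAL_COMPOSITES_ALPHA_GLC: dict[str, tuple[float, float]] = {
    "k3": (4.76e-10, 30.2),
    "k-3": (3.06e-11, 31.8),
    "k6": (1.56e-14, 36.3),
    "k-6": (1.28e-11, 32.3),
    "k11": (1.54e-10, 30.9),
    "k-11": (1.07e-9, 29.7),
}

#: Composite constants of the anionic track (three explicit waters).
ANIONIC_COMPOSITES_ALPHA_GLC: dict[str, tuple[float, float]] = {
    "k2": (8.80e1, 14.8),
    "k-2": (6.82e0, 16.3),
    "k7": (1.42e0, 17.3),
    "k-7": (6.49e-2, 19.1),
    "k10": (2.19e2, 14.3),
    "k-10": (4.01e-1, 18.0),
}

#: Observed constants at pH 8 (s^-1, formal barrier kcal/mol),
#: Me alpha-D-glucopyranoside, keyed by direction label.
OBSERVED_ALPHA_GLC_EXPERIMENTAL: dict[str, tuple[float, float]] = {
    "k1obs": (6.28e-5, 23.2),
    "k-1obs": (5.11e-5, 23.3),
    "k2obs": (5.06e-5, 23.3),
    "k-2obs": (1.01e-4, 22.9),
    "k3obs": (1.21e-3, 21.4),
    "k-3obs": (7.83e-5, 23.1),
}

OBSERVED_ALPHA_GLC_PREDICTED: dict[str, tuple[float, float]] = {
    "k1obs": (3.35e-4, 22.2),
    "k-1obs": (4.03e-5, 23.5),
    "k2obs": (3.15e-6, 25.0),
    "k-2obs": (4.50e-6, 24.8),
    "k3obs": (6.32e-4, 21.8),
    "k-3obs": (8.15e-5, 23.1),
}

OBSERVED_BETA_GLC_EXPERIMENTAL: dict[str, tuple[float, float]] = {
    "k1obs": (2.02e-4, 22.5),
    "k-1obs": (1.11e-4, 22.9),
    "k2obs": (1.15e-4, 22.8),
    "k-2obs": (1.28e-4, 22.8),
    "k3obs": (1.10e-3, 21.5),
    "k-3obs": (4.56e-5, 23.4),
}

#: Theoretical ([OH-] ratio to pH 8) and experimentally fitted pH
#: coefficients for acetyl migration in compound 1.
PH_COEFFICIENTS: dict[float, tuple[float, float]] = {
    9.0: (10.0, 7.1),
    8.0: (1.0, 1.0),
    7.5: (0.32, 0.35),
    7.0: (0.1, 0.085),
    6.0: (0.01, 0.0082),
}

#: Uniform rate multipliers vs the 100 mM phosphate reference buffer.
BUFFER_COEFFICIENTS: dict[int, float] = {50: 0.87, 500: 1.49}


def alpha_glc_mechanism(conditions: Conditions | None = None) -> MechanismSpec:
    """O2->O3 acetyl migration step of Me alpha-D-glucopyranoside.

    Only this step has published pKa values for both directions; the
    composite track constants come straight from the computed tables.
    """
    conditions = conditions or Conditions()
    step = MigrationStep(
        label="O2->O3",
        pka_fwd=PKA_ALPHA_GLC["2Ac"],
        pka_bwd=PKA_ALPHA_GLC["3Ac"],
        neutral=(
            NEUTRAL_COMPOSITES_ALPHA_GLC["k3"][0],
            NEUTRAL_COMPOSITES_ALPHA_GLC["k-3"][0],
        ),
        anionic=(
            ANIONIC_COMPOSITES_ALPHA_GLC["k2"][0],
            ANIONIC_COMPOSITES_ALPHA_GLC["k-2"][0],
        ),
    )
    return MechanismSpec(steps=(step,), conditions=conditions)
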