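# acylmig

Kinetics and mechanism of **acyl group migration in pyranosides**.

Ester acyl groups (acetyl, benzoyl, pivaloyl, 2-phenylpropanoyl, ...) on
partially protected sugars hop between adjacent hydroxyl positions —
typically clockwise O2 → O3 → O4 → O6 in hexopyranosides — and are slowly
lost to hydrolysis. This frustrates synthesis and purification of acylated
carbohydrates and matters for drug metabolism (acyl glucuronides).
`acylmig` provides the two computational layers needed to study the
phenomenon quantitatively from NMR time-course data:

1. **Network kinetics.** Migration plus hydrolysis is a linear first-order
   network, dc/dt = M c, over the acylated isomers and a deacylated sink.
   The package builds the generator M from a scheme (path A: four positions
   ending in a primary hydroxyl, two hydrolysis channels; path B: three
   secondary positions, one channel), solves it exactly by
   eigendecomposition, and estimates all rate constants (h⁻¹) from observed
   species-fraction time courses by bounded multi-start nonlinear least
   squares, with standard errors from the linearized covariance
   σ̂²(JᵀJ)⁻¹.

2. **Mechanistic rate algebra.** Each migration step runs through a cyclic
   orthoester intermediate on two parallel tracks — neutral (water-mediated)
   and anionic (after deprotonation of the attacking hydroxyl). With
   K_eq = 10^(−pKa) and [H⁺] = 10^(−pH), the observed constant of one
   direction is

   k_obs = k_neutral + k_anionic · K_eq/[H⁺],

   each track collapsing to a composite constant
   k = k_a·k_b/(k_−a + k_b) and every rate interconverting with a formal
   free-energy barrier via the Eyring equation
   k = κ(k_B T/h)·exp(−ΔG‡/RT). Reaction free-energy profiles along the
   migration path follow from observed rate pairs: successive minima spaced
   by RT·ln(k_bwd/k_fwd), maxima one formal barrier above each minimum.

A synthetic-data module generates NMR-like integral time courses (additive
Gaussian noise, truncation at zero, detection thresholds, buffer/pH
condition coefficients) with known ground truth, so the whole pipeline is
testable without raw spectra.

## Worked example

```python
import numpy as np
from acylmig import (Conditions, equilibrium_composition, fit_rates,
                     keq_from_pka, observed_rate, path_a)
from acylmig.datasets import (ANIONIC_COMPOSITES_ALPHA_GLC, COMPOUND_RATES,
                              NEUTRAL_COMPOSITES_ALPHA_GLC, PKA_ALPHA_GLC)
from acylmig.io import report_fit
from acylmig.synth import SynthDesign, generate_timecourse

# acetyl on Me alpha-D-glucopyranoside: simulate a noisy experiment, refit
rates = COMPOUND_RATES[1]
scheme = path_a()
tc, _ = generate_timecourse(
    SynthDesign(scheme=scheme, rates=rates, sigma=0.01, seed=7))
print(report_fit(fit_rates(tc, scheme, n_starts=5, seed=0)))

print("equilibrium composition (O2,O3,O4,O6):",
      np.round(equilibrium_composition(rates), 3))

# mechanistic prediction of the observed O2->O3 rate at pH 8
pred = observed_rate(NEUTRAL_COMPOSITES_ALPHA_GLC["k3"][0],
                     ANIONIC_COMPOSITES_ALPHA_GLC["k2"][0],
                     keq_from_pka(PKA_ALPHA_GLC["2Ac"]), Conditions(pH=8.0))
print(f"k1obs = {pred.k_obs:.3e} s^-1  (anionic fraction {pred.anionic_fraction:.6f})")
print(f"formal barrier = {pred.barrier:.1f} kcal/mol")
```

prints

```
constant    estimate        stderr  unit
k1          2.25E-01    ± 3.12E-03  h^-1
k-1         1.83E-01    ± 6.30E-03  h^-1
k2          1.89E-01    ± 5.84E-03  h^-1
k-2         3.75E-01    ± 3.23E-02  h^-1
k3          3.87E+00    ± 8.80E-01  h^-1
k-3         2.59E-01    ± 6.52E-02  h^-1
k4          3.15E-03    ± 2.23E-05  h^-1

equilibrium composition (O2,O3,O4,O6): [0.081 0.1   0.05  0.769]
k1obs = 1.108e-03 s^-1  (anionic fraction 1.000000)
formal barrier = 21.5 kcal/mol
```

The refit recovers the generating constants within their standard errors
(the fast O4→O6 pair carries the largest uncertainty, mirroring its weak
identifiability from fraction data). The equilibrium composition shows the
thermodynamic preference for the primary O6 ester, and the mechanistic
prediction shows the anionic pathway carrying essentially all of the
observed rate at pH 8 — the neutral water-mediated term is about six orders
of magnitude smaller.

A CLI mirrors the library for shell use:

```bash
acylmig synth --config scheme.json --sigma 0.01 --seed 1 --out tc.csv
acylmig fit --data tc.csv --config scheme.json --starts 5
acylmig mechanism --spec mech.json --ph 8
acylmig profile --kobs kobs.csv --out profile.csv
```

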