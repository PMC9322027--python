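# Methods

## The migration network model

Acyl migration between hydroxyl positions of a pyranoside is modeled as a
continuous-time linear first-order network over the acylated isomers plus a
single absorbing "hydrolyzed" sink:

    dc/dt = M c,      M[j, i] = rate of flow i -> j  (h^-1),

with migration edges only between *adjacent* positions along the path (the
two hydroxyls must be close in space; no direct O2 -> O6 transfer, no
migration to the anomeric position, no intermolecular transfer) and a
first-order hydrolysis channel from each acylated position to the sink.
Re-acylation from the sink is assumed impossible, making it absorbing.
Columns of M sum to zero, so total mole fraction is conserved exactly.

Two topologies cover the compound series:

* **path A** — four positions (O2, O3, O4, O6), the last primary; six
  migration constants k1, k-1, k2, k-2, k3, k-3 plus hydrolysis k4 (and
  optionally a distinct primary-position constant k5);
* **path B** — three secondary positions (pentopyranosides, rhamnose,
  fucose); four migration constants plus one hydrolysis constant k3.

By default hydrolysis is equal from every position (justified because it is
on average more than ten times slower than migration); the separate primary
constant is used for the bulky 2-phenylpropanoyl esters. For
ribopyranosides, whose hydrolysis constant was never determined, the
channel can be dropped entirely (`path_b(hydrolysis=False)`), fixing it to
zero in both simulation and fitting.

**Units.** All network constants are h^-1, matching the experimental
tables; the mechanism layer works in s^-1, and the only bridge between them
is an explicit factor-3600 unit conversion. The two k-namespaces
(experimental k1...k5 per edge, mechanistic step constants) are kept in
separate containers and never mixed.

**Initial condition.** A pure starting isomer (fraction 1 at the
synthesized position — O2 for the hexopyranosides, O4 where that was the
easier preparation). Initial purity is taken as exactly 1.0; no value was
ever reported.

## Exact simulation

The propagator exp(M t) is evaluated through the eigendecomposition of M
when the eigenbasis is well conditioned (condition number < 1e8), which
solves all sampling times at once. Otherwise — defective or nearly
defective generators, e.g. irreversible chains with equal rates — the code
falls back to a scaling-and-squaring matrix exponential per time point.
The contract is accuracy, not method: trajectories agree with a fixed-step
RK4 integration at dt = 1e-3 h to better than 1e-6, and row sums stay
within 1e-9 of 1 for study-scale rate sets (in practice ~1e-14).
Because the analytic solution lies in [0, 1], sub-roundoff excursions
(up to ~1e-8 for extreme ||M t|| encountered during optimizer trials) are
clipped back onto the physical range.

`time_to_equilibrium` zeroes the hydrolysis channels (the migration
sub-network pre-equilibrates on a much faster time scale), computes the
equilibrium composition by chaining the edge ratios k_fwd/k_bwd — detailed
balance holds on a chain — and bisects the first time at which every
acylated fraction is within the requested absolute tolerance of its
equilibrium value. An all-forward chain is reported as non-equilibrating.

## Rate-constant estimation

Unweighted least squares on the species-fraction residuals between the
exact simulation and the data, over all species and time points (several
time courses may be concatenated). No published weighting or censoring
scheme exists for the original analysis, so none is applied; points below
detection are whatever the generator (or instrument) recorded.

* **Optimizer:** `scipy.optimize.least_squares`, trust-region reflective,
  non-negativity bounds, tight tolerances (1e-14).
* **Multi-start:** the reported optimum is the best of `n_starts` runs
  (default 5): one fixed heuristic start (0.1 h^-1 migration, 0.01 h^-1
  hydrolysis) plus seeded log-uniform draws in [1e-4, 10] h^-1. All
  stochastic elements take an explicit seed (default 0).
* **Standard errors:** square roots of the diagonal of σ̂²(JᵀJ)⁻¹ at the
  optimum, σ̂² = RSS/(n − p). This is the package's own choice; the method
  behind the published ± values was never stated. If JᵀJ is singular
  (condition number > 1e12) the result is flagged non-identifiable and
  errors print as "n.d.". Estimates pinned at the non-negativity bound are
  flagged.
* **Condition coefficient:** a single multiplier c applied to all constants
  of a fixed reference set (buffer-strength or pH change) is fitted in
  log c by the same residual; an RMS residual above 0.05 flags the data as
  inconsistent with uniform scaling.

Noiseless data are recovered to ~1e-14 relative; the fit is invariant to
data-row order and rescales exactly with the time unit.

**Identifiability.** The fast O4 <-> O6 constants of the glucoside acetyl
system are intrinsically poorly determined from fraction data at the 1%
noise level: the linearized Cramér–Rao bound gives ~30% relative standard
error for k3 and k-3 under a 40-point design, whichever sampling grid is
used, because the O4 intermediate never exceeds a few percent of the total.
This matches the large published uncertainties on exactly these constants
(±50–60%). Recovery studies on synthetic data reproduce the bound: median
relative errors are 1–5% for the O2<->O3 / O3<->O4 constants and the
hydrolysis constant, but ~15–18% for the fast pair.

## Transition-state-theory layer

Physical constants: k_B = 1.380649e-23 J/K, h = 6.62607015e-34 J s,
R = 1.98720425e-3 kcal mol^-1 K^-1 (CODATA 2018); defaults T = 298.15 K,
transmission coefficient κ = 1, K_w = 1e-14. Activities are ignored:
[H+] = 10^(-pH), [OH-] = K_w/[H+].

* **Eyring conversion:** ΔG‡ = −RT ln(k h/(κ k_B T)); the inverse is exact
  and the round trip is accurate to ~1e-15 over rates from 1e-15 to 1e13
  s^-1. Validation against printed tables is done in the rate -> barrier
  direction, which is robust to printed rounding (barrier -> rate is
  exponentially sensitive and documented as approximate).
* **Composite two-step constants:** forward k_a·k_b/(k_-a + k_b), reverse
  k_-a·k_-b/(k_-a + k_b). Both directions share the steady-state
  denominator of the forward orthoester balance; note the asymmetry (a
  fully symmetric treatment would use k_a + k_-b in the reverse
  denominator — the shared-denominator convention is kept deliberately so
  that tabulated composite constants reproduce). The forward composite
  never exceeds k_a and reduces to the pre-equilibrium form
  k_a·k_b/k_-a when k_-a >> k_b.
* **Observed rates:** k_obs = k_neutral + k_anionic·K_eq/[H+], implemented
  strictly as a *sum* of two non-negative contributions; formulations that
  attach a negative sign to the neutral term are nonphysical for positive
  rates and are not reproduced. Both the full and the anionic-only
  ("simplified") modes are exposed, and the decomposition (neutral term,
  anionic term, anionic fraction) is always reported rather than collapsed
  into a single number.
* **Energy profiles:** first minimum at 0; each next minimum
  RT ln(k_bwd/k_fwd) away; each maximum one formal Eyring barrier of the
  forward observed rate above the preceding minimum. The construction is
  direction-independent (building the profile backwards and mirroring
  reproduces it to 1e-12). For the glucoside acetyl system the
  *experimental* observed rates place the O4 minimum ~0.4 kcal/mol above
  O3 — the descent of the minima from O2 to O6 is a trend, with the O6
  terminus as the global minimum ~1.3 kcal/mol below O2, not a strictly
  monotone staircase.

pKa values, step barriers and elementary rates are **inputs** to this
layer; no quantum chemistry is performed. Only the O2 -> O3 step of the
glucoside system has published pKa values for both directions (12.9 and
12.0), so the bundled `alpha_glc_mechanism()` covers that step.

## Synthetic data generator

Emulates integral-level species fractions from water-suppressed 1H NMR:

* exact network trajectory plus **additive Gaussian noise** (default
  σ = 0.01 per fraction) truncated at zero, *not* renormalized to sum to 1
  — each species integral is referenced independently to the OMe internal
  standard, so observed rows need not sum to exactly 1 (the readers accept
  a 0.05 slack on bounds and warn above 0.02 on row sums);
* optional detection threshold below which values are recorded as 0;
* default sampling design: 40 log-spaced points from 0.1 h to 5x the
  slowest relaxation time of the network, emulating campaigns that run
  from the first minutes to beyond a week for slow hydrolysis;
* condition series: one uniform multiplier per buffer/pH condition, each
  simulated with an independently spawned seed; with no explicit grid the
  sampling window derives from the scaled rates, so slower conditions are
  monitored longer, as an experimentalist would;
* determinism: the same seed always yields the same byte stream
  (`numpy.random.default_rng`).

The generator reproduces integral-level noise only: no peak shapes,
overlap, baseline or water-suppression artifacts, no scan-time coupling
between migration speed and noise. Passing recovery tests therefore show
that the estimator is correct and well calibrated *for this noise model*,
not that real spectra carry as much information.

## Problem sizes and tolerances used in the checks

Simulation/oracle agreement uses 100 random path-A networks (rates
log-uniform in [1e-4, 10] h^-1) at 1e-6 absolute; mass conservation 1e-9;
recovery studies 20 seeded replicates of the glucoside acetyl system at
σ = 0.01 with the default 40-point design and 5-start fits;
condition-coefficient recovery uses multipliers 0.87 and 1.49. These sizes
keep the full suite and the acceptance script in the minutes range on a
single CPU while leaving the statistical conclusions stable.

## Known limitations

* Hydrolysis is strictly irreversible and first order; buffer catalysis
  enters only through the single empirical uniform coefficient.
* The equal-hydrolysis constraint is a modeling switch, not inferred from
  data.
* Fractions are fitted as given; the package does not model the choice
  between sum-normalized and independently referenced integrals beyond
  accepting both through the same TimeCourse container.
* Energy-profile maxima are *formal* single-step barriers equivalent to
  the observed two-step rates; the real surface has an orthoester minimum
  between them.
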