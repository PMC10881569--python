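# Methods

`ernoed` implements model-based active learning for an in vitro enzymatic
reaction network operated in a microfluidic continuous stirred-tank
reactor (CSTR), together with the model-predictive screening that turns
the trained model into a multi-input multi-output (MIMO) controller of the
network's triphosphate output blend.  This note records the model, the
algorithms, the defaults and the design decisions, in that order.

## The kinetic model

The network is the reconstituted nucleotide salvage pathway: six enzymes
(UPRT, APRT, UMPK, GMPK, AK, PK) catalysing eight reactions over fifteen
chemical species,

```
UPRT   : uracil  + PRPP <-> UMP + PPi      (treated irreversible)
APRT   : adenine + PRPP <-> AMP + PPi      (treated irreversible)
UMPK   : UMP + ATP <-> UDP + ADP
GMPK   : GMP + ATP <-> GDP + ADP
AK     : AMP + ATP <-> 2 ADP
PK (x3): {UDP,GDP,ADP} + PEP <-> {UTP,GTP,ATP} + pyruvate
```

with a single pyruvate kinase shared between the three NDP substrates.
Rate laws are saturation kinetics with one binding site per substrate
pair and multiplicative site denominators:

* reversible reactions: `v = f_E (Vf * occ(S1) occ(S2) - Vr * occ(P1)
  occ(P2)) / (D1 * D2)` where `occ(X) = [X]/Km_X`, each `D` is `1 +` the
  summed occupancies of that site's binders, and `f_E` is the enzyme's
  dimensionless loading factor;
* UPRT and APRT are irreversible but carry competitive product binding
  (the nucleoside monophosphate at the base site, PPi at the PRPP site);
* the PK reactions share one nucleotide site whose denominator sums the
  occupancies of all three NDPs *and* all three NTPs (substrate
  competition), plus a shared PEP/pyruvate site.

This scheme yields 41 kinetic parameters: catalytic rates in mM/min at
reference enzyme loading, Michaelis constants in mM.  Base-ring moieties
(uracil, adenine, guanine) and the PEP/pyruvate skeleton balance in every
reaction, so they are conserved in batch operation — a property the test
suite checks to 1e-6.  The exact mechanistic forms are a modelling choice
of this package; `make_variant` produces alternatives (reversibility
toggles, competitive allosteric inhibition terms) for model
discrimination.

The CSTR mass balance for species s is

    dC_s/dt = (sum_i q_i(t) Cstock_{i,s} - q_tot(t) C_s)/V
              + sum_j N_{sj} v_j(C),

with V = 100 ul, six inlets each carrying one substrate stock, and
piecewise-constant pump schedules q(t).  Enzymes are immobilised on
retained beads: no outflow term, no degradation.  Simulations start from
zero chemical species (the reactor is pre-equilibrated with buffer) and
the integrator (LSODA with the analytic state Jacobian, generated
symbolically and JIT-compiled) is restarted at every flow switch.

### Default operating conditions

| quantity | default | rationale |
|---|---|---|
| reactor volume | 100 ul | microfluidic CSTR chamber |
| inlet stocks | uracil/GMP/adenine 5 mM, ATP 10 mM, PEP 40 mM, PRPP 20 mM | phosphate donor and PRPP in stoichiometric excess of the bases |
| pump levels | 0, 0.5, 1, 2 ul/min per inlet | total flows of a few ul/min fill a 15-30 min collection fraction from a 100 ul chamber; residence times 8-200 min match the enzymatic timescale |
| fraction interval | 15 min | offline HPLC sampling cadence |
| parameter bounds | rates 0.01-10 mM/min, Km 0.01-5 mM | plausible enzymology ranges; these are fitting bounds, not claims |

## Forward sensitivities and design scoring

Parameter sensitivities S = dC/dtheta obey the variational system
`dS/dt = (J_C - q_tot/V I) S + df/dtheta` with S(0) = 0.  Two integration
paths are provided:

* **exact** — the full augmented (15 x (1+41)-state) system integrated
  with LSODA; reporting-grade, validated against central finite
  differences to better than 1e-3 relative on every parameter;
* **staggered** — the state is solved first (stiff-capable, analytic
  Jacobian), then the linear sensitivity system is advanced with an
  exponential midpoint rule (frozen Jacobian per step, block matrix
  exponential), with the step capped at 1 min.  This is several-fold
  faster in awkward parameter regions and agrees with the exact path to
  ~1e-3; it backs fitting Jacobians and design scoring, where that
  accuracy is ample.

Designs are scored by D-optimality: scaled sensitivities
`s~ = (dy_o/dtheta_p) theta_p / sigma_o` (unit-free; sigma from the
measurement-noise model evaluated on the candidate's own trajectory) are
accumulated into the Fisher information matrix `F = sum s~ s~^T` over all
fraction times and observable species, and the score is
`log det(F + eps I)` with ridge `eps = 1e-8 trace(F)/p`.  Whether to
scale sensitivities and how to weight noise are not uniquely determined
by the problem; both choices are recorded here and in every score's
ridge field.  Fitness of a candidate schedule is the mean D-score over
the current top parameter-ensemble members (robust design under
parameter uncertainty).

The design space is discrete: per segment and inlet one of the four pump
levels (at least one inlet positive per segment).  The optimiser is a
generational genetic algorithm — tournament selection (size 3), one-point
crossover (p = 0.7), per-gene mutation (p = 1/genome length, to a random
*other* level), elitism (2) — with memoised fitness.  Defaults: 12
segments x 60 min, population 32, 40 generations; the loop and the
acceptance runs use smaller instances (documented below).

## Fitting and the ensemble

The fit score is the heteroscedastic weighted sum of squares pooled over
all experimental rounds, each simulated under its own flow profile and
enzyme loading.  Optimisation runs in log-parameter space under bound
constraints (`scipy.optimize.least_squares`, trust-region reflective)
with the exact residual Jacobian from forward sensitivities; starts are
log-uniform over the bounds (multistart, default 64, plus optional warm
starts from a previous ensemble).  A simulation failure during fitting
returns a large finite penalty so the optimiser can retreat.

Uncertainty is carried by the *ensemble of accepted fits*: terminal
points scoring within 15% of the best score, deduplicated at 1e-3
relative parameter distance, capped at the 20 best.  Predictions are
reported as mean +/- population SD over member simulations; the
prediction error of an ensemble against observations is the mean over
the three triphosphates of the mean relative deviation
`100 |mean_sim - obs| / obs` (zero observations are excluded and
flagged).

Because a handful of multistart points cannot sample a 41-dimensional
acceptance region stably, the per-parameter *width* of that region is
estimated asymptotically (`acceptance_region_widths`): from the
Gauss-Newton information matrix H at the best fit, the marginal
half-width along parameter p is `sqrt(0.15 chi2_best (H^-1)_pp)`, with
the declared bounds entering as a diagonal regulariser so unidentified
directions saturate at the bounds width instead of diverging.  This is
the quadratic-model analogue of the accepted-fit spread and is what the
shrinkage checks compare between early- and late-round datasets.

## The active-learning loop

One iteration: (1) evolve a flow schedule against the current ensemble;
(2) run the experiment — here the virtual experimenter; (3) use the
*previous* ensemble to predict the fresh round (held-out test data) and
record mean NTP error, per-species errors, two-sigma coverage and band
width; (4) refit on the accumulated dataset.  The cycle starts from a
manually designed calibration round — a staircase in which every inlet
visits all three positive pump levels with all-low baselines between —
and stops when the prediction error is below 10%, improves by less than
10% relative, or after 3 iterations (all configurable).  Every stage
seed is derived from the master seed and the stage name, so a whole loop
is a pure function of (model, truth seed, configs, master seed).

## MIMO control

The trained ensemble acts as a forward map from constant inlet flows to
steady-state outputs.  Steady states are found by a Newton solve seeded
from the dilution-only fixed point (ensemble members warm-start each
other), falling back to integration over ten residence times plus a
Newton polish; non-converged members flag the outcome.  For each
condition the ensemble yields NTP means and SDs, the ATP:UTP:GTP ratio
(normalised to sum 1, from the means) and the conversion efficiency

    eff = 100 (UTP + GTP + (ATP_out - ATP_feed))
          / (uracil_feed + GMP_feed + adenine_feed),

feeds taken as dilution-weighted inflow concentrations `q_i Cstock_i /
q_tot`.  Negative net ATP subtracts as-is (no clamping).  Condition
screening samples inlet flows uniformly within the pump range (0-2
ul/min per inlet); survivors of the efficiency constraint (default 60%)
are thinned by greedy farthest-point selection in (ratio simplex x
min-max-scaled total feed concentration) space, seeded by the survivor
farthest from the uniform-blend centroid.  When seven or more picks are
requested, the last slot deliberately duplicates the first pick's ratio
(a repeated-blend control condition).

## The virtual experimenter

The synthetic stand-in for the wet lab serves two purposes: it makes the
full pipeline executable with no external data, and it defines the study
conditions under which the package's claims are tested.

* **Ground truth.**  Michaelis constants are drawn log-uniformly from
  the central half (log scale) of their bounds.  Forward catalytic rates
  are drawn log-uniformly over 0.32-3.2 mM/min: immobilised-enzyme
  loading in the study was balanced from per-enzyme activity assays, so
  effective activities are workable and of order 1 mM/min rather than
  scattered over the three-decade fitting range.  PK reverse rates are
  drawn one to two decades below their forward rates: PEP
  phosphotransfer is strongly exergonic, so the reaction is mechanically
  reversible but thermodynamically forward-biased.  A draw is accepted
  only if the calibration round shows all three triphosphates above the
  quantification limit *and* at least 1% of a fixed 256-condition probe
  reaches 60% conversion efficiency — i.e. the truth represents a
  functional salvage network capable of the control task the study
  demonstrates.  Draw counts are recorded; everything is deterministic
  per seed.
* **Measurement noise.**  HPLC-like: sigma(C) = max(0.01 mM, 0.05 C),
  independent Gaussian, truncated at zero; values below the 0.005 mM
  quantification limit are reported at the limit with inflated sigma.
  The noise floor makes low-concentration species relatively noisy,
  which is what degrades predictions at low total substrate input.

What the generator does **not** emulate: bead-loading variability,
chromatographic drift, carryover between fractions, or model mismatch —
the fitted model class contains the truth.  Passing tests therefore
demonstrate that the design/fit/control machinery works under realistic
noise and partial observability (8 of 15 species); they do not
demonstrate robustness to a mis-specified mechanism, which the variant
machinery (`make_variant`) exists to probe.

## Numerical choices

* Integration tolerances: simulation rtol 1e-8/atol 1e-10 (reporting),
  1e-7/1e-9 inside fitting residuals; exact sensitivities 1e-8/1e-10;
  staggered path 1e-6/1e-8 with a 1-min step cap.
* Halving tolerances changes reported trajectories by < 1e-5 relative;
  species never undershoot zero by more than ~10x the absolute
  tolerance (consumption terms vanish at zero concentration).
* Steady-state acceptance: `||dC/dt||_inf <= 1e-9 max(1, ||C||_inf)`
  and concentrations above -1e-9.
* D-score ridge 1e-8 trace(F)/p; rank-deficient information without a
  ridge raises rather than returning -inf.
* Fit Jacobians are clipped at 1e8 (runaway sensitivities carry no
  usable direction information).
* Dedup threshold for ensemble members: 1e-3 maximum absolute
  log-parameter distance.

## Desk-scale problem sizes

The full-scale defaults (12 x 60 min designs, population 32, 40
generations, 64 starts) describe how the tool is meant to be run.  The
test suite and the acceptance script exercise the identical code paths
at desk scale, chosen once: designs of 3-4 segments x 20-30 min,
populations 8 with 3-4 generations, 4-5 multistart fits capped at 12-15
Jacobian evaluations with up to 3 warm starts, 3 loop iterations after
calibration, 5,000-condition control screens with up to 20 ensemble
members, and 3-5 independent seeds per experiment.  At these sizes the
loop's predictive power improves from roughly 3-6% to 1-4% mean NTP
error on held-out rounds; individual parameters remain partially
unidentifiable (correlated sensitivities), which is precisely the
regime the methodology targets: control-grade predictions without full
parameter identification.

## Known limitations

* No adjoint sensitivities; the forward variational system scales
  linearly in the parameter count.
* No thermodynamic (Haldane) consistency is enforced between Vf, Vr and
  the Km values during fitting — rates are free within bounds.
* The ensemble-of-best-fits heuristic is not a posterior; its spread is
  a practical uncertainty currency, not a calibrated credible interval.
* Steady-state screening assumes a unique reachable steady state per
  condition; the integration fallback makes this the steady state
  reachable from the buffer-equilibrated start.
* SBML export is not implemented; the bespoke text format is the
  interchange form.
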