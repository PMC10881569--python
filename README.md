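# ernoed

Optimal experimental design and model-based control of in vitro
enzymatic reaction networks in flow.

## The problem

Kinetic (ODE) models of reconstituted enzymatic reaction networks are
the tool of choice for steering such networks toward target outputs, but
training them is data-limited: steady-state batch measurements are
kinetically uninformative, and with only a subset of species observable
the rate parameters are heavily correlated ("sloppy").  `ernoed`
implements the remedy for a concrete system — the nucleotide salvage
pathway (6 enzymes, 8 reactions, 15 species) operated in a 100 ul
continuous stirred-tank reactor with six substrate inlets and offline
HPLC readout of 8 species:

1. **Simulate** the network under arbitrary piecewise-constant inflow
   schedules (sympy-generated, numba-compiled kinetics; stiff-capable
   integration with exact Jacobians).
2. **Design** maximally informative schedules by maximising the
   D-criterion `log det F` of the Fisher information matrix
   `F = sum_k sum_o s~_ok s~_ok^T`, built from forward parameter
   sensitivities `s~ = (dy_o/dtheta_p) theta_p / sigma_o`, with a
   genetic algorithm over discrete pump levels.
3. **Fit** the 41 kinetic parameters to accumulated time-course rounds
   by multistart bound-constrained least squares in log space, keeping
   the *ensemble* of fits within 15% of the best score as the
   uncertainty currency.
4. **Iterate** design -> experiment -> test-on-held-out-round -> refit
   (active learning), stopping when predictive power no longer improves.
5. **Control** the trained network as a MIMO system: screen thousands of
   random inlet-flow combinations through the ensemble to steady state,
   filter on a minimum conversion efficiency
   `100 (UTP + GTP + ATP_out - ATP_feed) / (uracil + GMP + adenine feed)`,
   and select diverse ATP:UTP:GTP blends to realise.

A seeded **virtual experimenter** (hidden ground-truth kinetics plus an
HPLC-like noise model) stands in for the wet lab, so the whole cycle is
reproducible end to end in silico.  The package is aimed at
computational biologists and flow chemists who want to train and use
control-grade kinetic models of multi-enzyme pathways.

## A worked example

```bash
python examples/03_design_experiment.py
```

prints (seeded, so exactly reproducible):

```
evolved design D-score :     4.35 (41 evaluations)
random designs D-score :   -23.84 (mean of 10)
evolved inflow schedule (ul/min, rows = segments, cols = uracil, GMP, adenine, ATP, PEP, PRPP):
[[0.5 1.  2.  0.5 0.5 2. ]
 [2.  0.  0.5 1.  2.  1. ]
 [0.5 1.  1.  0.5 2.  0. ]
 [1.  1.  1.  2.  0.5 0.5]]
```

The D-score is the log-determinant of the 41x41 Fisher information
matrix: the evolved four-segment schedule buys ~28 nats of information
volume over random pulsing by driving flow transitions that decorrelate
parameter sensitivities.  The other examples walk through simulation
(`01`), sensitivity/FIM analysis (`02`), ensemble fitting (`04`), the
full active-learning loop (`05`) and MIMO control with ground-truth
verification (`06`).

A thin CLI mirrors the library for shell use:
`ernoed simulate|sensitivities|design|fit|predict|loop|control|synth`
(every run writes a `manifest.json` with version, input hashes and
seeds).

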