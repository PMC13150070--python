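"""Run the outer Bayesian loop: trade growth against medium cost.

A short run on the 2-nutrient toy (random initialization, then batched
acquisition of new media), printing the budget accounting and the Pareto
front it finds. Growth is in h^-1; cost is the priced sum of supplied bounds.
"""

import logging

import medbo as mb
from medbo import benchmarks

logging.getLogger("medbo.medium").setLevel(logging.ERROR)

model, spec, prices, objective, _ = benchmarks.standard_toy()

config = mb.OptimizationConfig(n_init=15, n_iter=8, batch_size=3, seed=0)
dataset = mb.run(model, spec, prices, objective, ("growth", "cost"), config)
print(f"evaluated media: {len(dataset)} = {config.n_init} init "
      f"+ {config.n_iter} iterations x {config.batch_size}")

front = mb.extract_front(dataset)
print(f"Pareto front: {len(front)} media (no member can grow faster "
      "without costing more)")
for x, y in zip(front.X_members[:5], front.Y_members[:5]):
    print(f"  bounds ({x[0]:.2f}, {x[1]:.2f})  growth {y[0]:.3f} h^-1  "
          f"cost {-y[1]:.3f}")
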