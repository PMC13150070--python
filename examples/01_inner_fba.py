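"""Solve the inner flux-balance problem on a synthetic toy network.

Builds a 2-nutrient network whose growth optimum has the closed form
min(u1/a1, u2/a2), applies a medium, and solves standard and parsimonious FBA.
"""

import medbo as mb

spec = mb.ToyGemSpec(
    n_nutrients=2, pathway_yields=(1.0, 2.0), prices=(1.0, 0.5), box_upper=(4.0, 4.0)
)
model, closed_form = mb.make_toy_gem(spec)
objective = mb.make_combined_objective(model, 1.0)

medium = {"IMP_X0": 3.0, "IMP_X1": 4.0}
constrained = mb.apply_medium(model, medium)
sol = mb.solve_fba(constrained, objective)
print(f"FBA growth rate: {sol.objective_value:.4f} h^-1 "
      f"(closed form min(3/1, 4/2) = {closed_form([3, 4]):.4f})")

# a redundant network: plain FBA may split flux, pFBA picks the short route
redundant = mb.make_redundant_pathway_model()
obj = mb.make_combined_objective(redundant, 1.0)
pfba = mb.solve_pfba(redundant, obj)
print(f"pFBA total |flux| on the redundant toy: {pfba.total_flux:.4f} "
      f"(3x throughput: import + one conversion + growth)")
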