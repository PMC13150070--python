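"""Emit editable configuration templates for the published case studies.

Each template lists the named medium components with baseline values and
search-box limits; prices are placeholders to be replaced with vendor quotes.
The genome-scale models themselves (iML1515, iJO1366, iBsu1103) are fetched
separately — see medbo.casestudies.load_bigg_model.
"""

import medbo as mb

for case in ("ecoli_m9", "ecoli_antibody", "bsubtilis_surfactin"):
    spec, prices, extras = mb.make_case_study_config(case)
    ratio = extras["fba_ratio"]
    print(f"{case}: {len(spec.decision_names)} decision variables, "
          f"FBA biomass:production ratio {ratio[0]:g}:{ratio[1]:g}")
    print("  components:", ", ".join(spec.decision_names))

print("\nglucose flux cap:", mb.concentration_to_flux(20.0, 0.5),
      "mmol/gDW/h (from 20 mM at conversion factor 0.5)")
print("growth-rate band from a 42 +/- 12 min doubling time:",
      f"{mb.doubling_time_to_growth(54):.2f} - {mb.doubling_time_to_growth(30):.2f} h^-1")
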