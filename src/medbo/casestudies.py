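"""Optional helpers for the published genome-scale case studies.

The E. coli and B. subtilis studies run on BiGG models (iML1515, iJO1366,
iBsu1103) that are too large to ship; :func:`load_bigg_model` fetches them on
demand with a local cache. Everything here degrades with an explicit error
when offline — the rest of the package is fully usable without downloads via
the synthetic fixtures in :mod:`medbo.toys`.
"""

from __future__ import annotations

from pathlib import Path

from .model_io import MetabolicModel, read_model

__all__ = ["load_bigg_model", "wildtype_growth_rates", "DEFAULT_CACHE"]

BIGG_URL = "http://bigg.ucsd.edu/static/models/{model_id}.json"
DEFAULT_CACHE = Path("scratch/models")


def load_bigg_model(
    model_id: str,
    cache_dir: str | Path = DEFAULT_CACHE,
    timeout: float = 15.0,
) -> MetabolicModel:
    """Load a BiGG model by id, downloading to a local cache if needed.

    The acyl-ACP metabolite identifiers needed to graft lipopeptide
    production reactions onto iBsu1103 are not standardized; pass your
    model's identifiers explicitly when building recipes rather than relying
    on guesses.
    """
    cache_dir = Path(cache_dir)
    path = cache_dir / f"{model_id}.json"
    if not path.exists():
        import urllib.request

        cache_dir.mkdir(parents=True, exist_ok=True)
        url = BIGG_URL.format(model_id=model_id)
        try:
            with urllib.request.urlopen(url, timeout=timeout) as resp:
                data = resp.read()
        except OSError as exc:
            raise ConnectionError(
                f"cannot download {model_id} from {url} and no cached copy at "
                f"{path}; place the BiGG JSON there to run this case study offline"
            ) from exc
        path.write_bytes(data)
    return read_model(path, dialect="bigg-json")


def wildtype_growth_rates(model: MetabolicModel | None = None) -> dict[str, float]:
    """Benchmark growth rates of wild-type E. coli (iML1515), h^-1.

    Two configurations are reported rather than reconciled, because the
    glucose-capped prediction and the maximum over an M9-style search box
    correspond to different oxygen/trace-metal settings:

    * ``glucose_capped`` — glucose uptake capped at the calibrated
      10 mmol gDW^-1 h^-1, all other imports at the model's defaults;
    * ``m9_box_max`` — additionally capping oxygen uptake at
      20 mmol gDW^-1 h^-1, the midpoint of observed uptake rates.

    Downloads iML1515 on first use unless a model is passed in.
    """
    from .fba import apply_medium, make_combined_objective, solve_fba

    if model is None:
        model = load_bigg_model("iML1515")
    objective = make_combined_objective(model, 1.0)

    capped = apply_medium(model, {"EX_glc__D_e": 10.0})
    sol1 = solve_fba(capped, objective)
    boxed = apply_medium(model, {"EX_glc__D_e": 10.0, "EX_o2_e": 20.0})
    sol2 = solve_fba(boxed, objective)
    return {
        "glucose_capped": sol1.flux(model, model.biomass_reaction),
        "m9_box_max": sol2.flux(model, model.biomass_reaction),
    }
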