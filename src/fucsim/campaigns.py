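"""Simulation campaigns: redox scenarios, oxygen sweep, substrate scan, strain series.

Each campaign is a pure function of (model, configuration, grid): rerunning
writes byte-identical CSV. The production envelopes are computed with a
two-step protocol — maximize growth first, then maximize product secretion at
a required growth level — because a single biomass-objective FBA carries zero
product flux by construction (secretion is always strictly growth-suboptimal).

The growth floor used by :func:`oxygen_sweep` and :func:`substrate_ratio_scan`
is **fixed across the grid**: ``biomass_fraction`` × the maximum growth under
the model's *reference* condition (its bounds as configured, before any grid
override — aerobic and glucose-replete by default). A fixed floor makes the
product column a true trade-off envelope — monotone in the relaxed bound
because the feasible sets are nested — and reproduces the biological reading
of the campaigns: without oxygen the required growth is unreachable, so no
fuculose can be made at that operating point, and glucose uptake at least
matching lactaldehyde uptake is needed before production turns on. Rows whose
growth floor is unreachable report product 0 with status ``growth_infeasible``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fba import FluxSolution, flux_variability, solve_fba
from .model import ConstraintModel, ModelError, apply_deletions

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "DEFAULT_STRAINS",
    "DIAGNOSTIC_REACTIONS",
    "apply_scenario",
    "run_redox_scenarios",
    "oxygen_sweep",
    "substrate_ratio_scan",
    "strain_series",
    "write_campaign_csv",
]

#: fluxes reported alongside every scenario: product/substrate exchanges and
#: the competing LAD sinks
DIAGNOSTIC_REACTIONS = ("EX_fcl", "EX_lad", "EX_pdo", "FUCO", "FCPA", "ALDA")

#: the engineered strain series (deletion sets cumulative along the series)
DEFAULT_STRAINS: tuple[tuple[str, frozenset[str]], ...] = (
    ("wild-type", frozenset()),
    ("Fuc1", frozenset({"fucI", "fucK"})),
    ("Fuc2", frozenset({"fucI", "fucK", "tpiA"})),
    ("Fuc3", frozenset({"fucI", "fucK", "tpiA", "fucO"})),
    ("Fuc4", frozenset({"fucI", "fucK", "tpiA", "fucO", "aldA"})),
)


@dataclass
class ScenarioSpec:
    """A named what-if: bound overrides plus gene deletions."""

    name: str
    bound_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    deletions: frozenset[str] = frozenset()
    objective: str = "BIOMASS"
    secondary_objective: str | None = None


@dataclass
class ScenarioResult:
    name: str
    status: str
    growth: float
    product_max: float
    table: pd.DataFrame  # columns: reaction, flux, fva_min, fva_max


def _require_reactions(model: ConstraintModel, rids) -> None:
    missing = [r for r in rids if not model.has_reaction(r)]
    if missing:
        raise ModelError(
            f"model lacks reaction(s) {missing}; extend the host with the "
            "fuculose pathway first"
        )


def apply_scenario(model: ConstraintModel, spec: ScenarioSpec) -> ConstraintModel:
    """Copy of ``model`` with the scenario's bounds and deletions applied."""
    out = model.copy()
    for rid, (lb, ub) in spec.bound_overrides.items():
        if lb > ub:
            raise ValueError(f"override for '{rid}' has lb {lb} > ub {ub}")
        rxn = out.get_reaction(rid)  # KeyError if absent
        rxn.lower_bound, rxn.upper_bound = float(lb), float(ub)
    if spec.deletions:
        out = apply_deletions(out, spec.deletions)
    return out


def _with_growth_floor(model: ConstraintModel, biomass: str, floor: float) -> ConstraintModel:
    out = model.copy()
    rxn = out.get_reaction(biomass)
    rxn.lower_bound = max(rxn.lower_bound, floor)
    return out


def _max_product_at_floor(
    model: ConstraintModel, biomass: str, product: str, floor: float
) -> FluxSolution:
    return solve_fba(_with_growth_floor(model, biomass, floor), product)


def run_redox_scenarios(
    model: ConstraintModel,
    biomass: str = "BIOMASS",
    o2_exchange: str = "EX_o2",
    aerobic_bound: float = -20.0,
    product: str = "EX_fcl",
    product_fraction: float = 0.5,
    diagnostics: tuple[str, ...] = DIAGNOSTIC_REACTIONS,
) -> dict[str, ScenarioResult]:
    """Aerobic vs anaerobic flux tables for the extended model.

    Per scenario: the maximum growth, an optimal flux vector, flux-variability
    ranges (at 100 % of optimum) for the diagnostic reactions — the basis for
    the claims that anaerobically all LAD is diverted to 1,2-PDO with no
    fuculose flux — and the maximum product secretion at
    ``product_fraction`` × that scenario's growth optimum. An infeasible
    scenario is recorded, not fatal.
    """
    _require_reactions(model, [biomass, o2_exchange, product])
    scenarios = {
        "aerobic": ScenarioSpec("aerobic", {o2_exchange: (aerobic_bound, 0.0)}),
        "anaerobic": ScenarioSpec("anaerobic", {o2_exchange: (0.0, 0.0)}),
    }
    results: dict[str, ScenarioResult] = {}
    diag = [r for r in diagnostics if model.has_reaction(r)]
    for name, spec in scenarios.items():
        scenario_model = apply_scenario(model, spec)
        sol = solve_fba(scenario_model, biomass)
        if not sol.optimal:
            results[name] = ScenarioResult(name, sol.status, float("nan"),
                                           float("nan"), pd.DataFrame())
            continue
        fva = flux_variability(scenario_model, biomass, fraction=1.0, reactions=diag)
        table = pd.DataFrame(
            {
                "reaction": diag,
                "flux": [sol.fluxes[r] for r in diag],
                "fva_min": [fva[r][0] for r in diag],
                "fva_max": [fva[r][1] for r in diag],
            }
        )
        prod = _max_product_at_floor(
            scenario_model, biomass, product, product_fraction * sol.objective_value
        )
        results[name] = ScenarioResult(
            name, "optimal", sol.objective_value,
            prod.objective_value if prod.optimal else 0.0, table,
        )
    return results


def _sweep(
    model: ConstraintModel,
    control_exchange: str,
    grid,
    biomass: str,
    product: str,
    biomass_fraction: float,
    control_label: str,
    diagnostics: tuple[str, ...] = ("FUCO", "FCPA", "EX_pdo"),
) -> pd.DataFrame:
    if grid is None or len(list(grid)) == 0:
        raise ValueError("grid must be non-empty")
    grid = sorted((float(g) for g in grid), key=abs)
    if any(g > 0 for g in grid):
        raise ValueError("grid values are uptake lower bounds and must be <= 0")
    _require_reactions(model, [biomass, control_exchange, product])
    diag = [r for r in diagnostics if model.has_reaction(r)]

    def at(bound: float) -> ConstraintModel:
        out = model.copy()
        out.get_reaction(control_exchange).lower_bound = bound
        return out

    # growth floor fixed at the model's as-configured reference condition
    # (its default bounds, before any grid override)
    ref = solve_fba(model, biomass)
    if not ref.optimal:
        raise ModelError(f"reference condition of the model is {ref.status}")
    floor = biomass_fraction * ref.objective_value

    rows = []
    for bound in grid:
        sub = at(bound)
        growth = solve_fba(sub, biomass)
        if not growth.optimal:
            rows.append({control_label: bound, "max_growth": float("nan"),
                         "max_fuculose": float("nan"), "status": growth.status,
                         **{f"{r}_flux": float("nan") for r in diag}})
            continue
        prod = _max_product_at_floor(sub, biomass, product, floor)
        if prod.optimal:
            row = {control_label: bound, "max_growth": growth.objective_value,
                   "max_fuculose": prod.objective_value, "status": "ok",
                   **{f"{r}_flux": prod.fluxes[r] for r in diag}}
        else:
            # required growth unreachable under this bound: no production here
            row = {control_label: bound, "max_growth": growth.objective_value,
                   "max_fuculose": 0.0, "status": "growth_infeasible",
                   **{f"{r}_flux": float("nan") for r in diag}}
        rows.append(row)
    return pd.DataFrame(rows)


def oxygen_sweep(
    model: ConstraintModel,
    o2_grid=None,
    biomass_fraction: float = 0.5,
    biomass: str = "BIOMASS",
    product: str = "EX_fcl",
    o2_exchange: str = "EX_o2",
) -> pd.DataFrame:
    """Growth and fuculose envelopes across oxygen-uptake bounds.

    Default grid: 0 to −20 in steps of −2 (anaerobic to fully aerobic for the
    mini-core). Both reported columns are non-decreasing in |O2 bound|; see the
    module docstring for the fixed-floor protocol.
    """
    if o2_grid is None:
        o2_grid = [-2.0 * k for k in range(11)]
    return _sweep(model, o2_exchange, o2_grid, biomass, product,
                  biomass_fraction, "o2_lower_bound")


def substrate_ratio_scan(
    model: ConstraintModel,
    glc_grid=None,
    lad_bound: float = -5.0,
    biomass_fraction: float = 0.5,
    biomass: str = "BIOMASS",
    product: str = "EX_fcl",
    glc_exchange: str = "EX_glc",
    lad_exchange: str = "EX_lad",
) -> pd.DataFrame:
    """Fuculose envelope across glucose-uptake bounds at fixed LAD supply.

    Production requires glucose as the DHAP source: the column is 0 at a zero
    glucose bound and non-decreasing in |glucose bound|.
    """
    if glc_grid is None:
        glc_grid = [0.0, -1.0, -2.5, -5.0, -10.0]
    work = model.copy()
    work.get_reaction(lad_exchange).lower_bound = float(lad_bound)
    return _sweep(work, glc_exchange, glc_grid, biomass, product,
                  biomass_fraction, "glc_lower_bound")


def strain_series(
    model: ConstraintModel,
    strain_defs=None,
    biomass_fraction: float = 0.5,
    biomass: str = "BIOMASS",
    product: str = "EX_fcl",
    track: tuple[str, ...] = ("FUCI", "FCLK", "TPI", "FUCO", "ALDA"),
) -> pd.DataFrame:
    """Growth/product envelope and competing-reaction ranges per strain.

    Default series: wild-type, then Fuc1 (ΔfucI ΔfucK), Fuc2 (+ΔtpiA), Fuc3
    (+ΔfucO), Fuc4 (+ΔaldA). Deletions go through the GPR machinery
    (:func:`fucsim.model.apply_deletions`); unknown genes are warned about and
    ignored. Tracked reactions get flux-variability ranges at the strain's
    growth optimum — a deleted gene's reaction must show range (0, 0).
    """
    strain_defs = list(strain_defs) if strain_defs is not None else list(DEFAULT_STRAINS)
    _require_reactions(model, [biomass, product])
    tracked = [r for r in track if model.has_reaction(r)]

    rows = []
    for name, deletions in strain_defs:
        strain = apply_deletions(model, set(deletions))
        growth = solve_fba(strain, biomass)
        if not growth.optimal:
            rows.append({"strain": name, "deletions": ";".join(sorted(deletions)),
                         "status": growth.status, "max_growth": float("nan"),
                         "max_fuculose": float("nan")})
            continue
        prod = _max_product_at_floor(
            strain, biomass, product, biomass_fraction * growth.objective_value
        )
        fva = flux_variability(strain, biomass, fraction=1.0, reactions=tracked)
        row = {
            "strain": name,
            "deletions": ";".join(sorted(deletions)),
            "status": "ok",
            "max_growth": growth.objective_value,
            "max_fuculose": prod.objective_value if prod.optimal else 0.0,
        }
        for rid in tracked:
            row[f"{rid}_fva_min"], row[f"{rid}_fva_max"] = fva[rid]
        rows.append(row)
    return pd.DataFrame(rows)


def write_campaign_csv(table: pd.DataFrame, path) -> None:
    """Write a campaign table deterministically (6-decimal floats)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(table.to_csv(index=False, float_format="%.6f"))
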