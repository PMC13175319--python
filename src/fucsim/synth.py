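"""Synthetic inputs: the bundled mini-core network, toy LPs, fermentation curves.

Nothing in this package is downloaded. The "mini-core" built here emulates the
functional blocks of the *E. coli* core metabolic model that the fuculose
analysis exercises — glucose uptake, upper glycolysis with the DHAP/G3P split
and triose-phosphate isomerase, lower glycolysis, respiration, fermentative
overflow (lactate, acetate), a lumped biomass reaction and ATP maintenance —
in ~20 reactions, so that every campaign property is derivable from stated
stoichiometry. Any real BiGG-dialect core model loads through
:func:`fucsim.model.parse_model` and runs through the same pipeline.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fermentation import MW_FUCULOSE, TimeCourse
from .model import ConstraintModel, DEFAULT_LOWER, DEFAULT_UPPER, Metabolite, Reaction
from .pathway import PathwayOptions, extend_with_fuculose_pathway

__all__ = [
    "MiniCoreSpec",
    "build_mini_core",
    "build_extended_mini_core",
    "build_fuculose_motif",
    "random_toy_model",
    "FermentationParams",
    "simulate_timecourse",
]


@dataclass
class MiniCoreSpec:
    """Tunable study conditions of the mini-core host.

    Uptake bounds are magnitudes in mmol·gDW⁻¹·h⁻¹ (applied as negative lower
    bounds on the exchanges): glucose 10 and lactaldehyde 5 mirror the 10 g/L
    glucose : 5 mM LAD medium ratio in round numbers; oxygen 20 is a
    conventional fully-aerobic cap. ``maintenance`` is the non-growth ATP
    demand; biomass costs 1 pyruvate + 10 ATP per unit; ``po_ratio`` is the
    ATP recovered per NADH respired.
    """

    glc_uptake: float = 10.0
    lad_uptake: float = 5.0
    o2_uptake: float = 20.0
    maintenance: float = 1.0
    biomass_pyr: float = 1.0
    biomass_atp: float = 10.0
    po_ratio: float = 2.0

    def __post_init__(self) -> None:
        if self.maintenance < 0:
            raise ValueError("maintenance must be >= 0")


def _met(mid: str, name: str, formula: str | None = None) -> Metabolite:
    return Metabolite(id=mid, name=name, formula=formula)


def build_mini_core(spec: MiniCoreSpec | None = None) -> ConstraintModel:
    """Deterministic mini-core host model (objective: BIOMASS).

    Internal reactions: GLYC_UP (glc + 2 atp → dhap + g3p + 2 adp), TPI
    (dhap ⇌ g3p, gene tpiA), GLYC_LO (g3p + 2 adp + nad → pyr + 2 atp + nadh),
    RESP (nadh + ½ o2 + P/O·adp → nad + P/O·atp), LDH, ACK, BIOMASS, ATPM
    (lower bound = maintenance). Boundary plumbing (transport + exchange) is
    provided for glucose, oxygen, acetate, lactate and biomass, plus freely
    exchanged water and inorganic phosphate so that pathway reactions added by
    :func:`fucsim.pathway.extend_with_fuculose_pathway` are elementally
    balanced. Lumped host reactions elide CO2/water and carry no formulas, so
    the mass-balance checker skips them by design.
    """
    spec = spec or MiniCoreSpec()
    m = ConstraintModel(id="mini_core", genes=["tpiA"], objective="BIOMASS")
    m.metabolites = [
        _met("glc_e", "glucose (extracellular)"),
        _met("glc_c", "glucose"),
        _met("o2_e", "oxygen (extracellular)"),
        _met("o2_c", "oxygen"),
        _met("dhap_c", "dihydroxyacetone phosphate", "C3H7O6P"),
        _met("g3p_c", "glyceraldehyde 3-phosphate"),
        _met("pyr_c", "pyruvate"),
        _met("nad_c", "NAD+"),
        _met("nadh_c", "NADH"),
        _met("atp_c", "ATP"),
        _met("adp_c", "ADP"),
        _met("lac_c", "lactate", "C3H6O3"),
        _met("lac_e", "lactate (extracellular)", "C3H6O3"),
        _met("ac_c", "acetate"),
        _met("ac_e", "acetate (extracellular)"),
        _met("biomass_c", "biomass"),
        _met("biomass_e", "biomass (boundary)"),
        _met("h2o_c", "water", "H2O"),
        _met("h2o_e", "water (extracellular)", "H2O"),
        _met("pi_c", "phosphate", "H3O4P"),
        _met("pi_e", "phosphate (extracellular)", "H3O4P"),
    ]

    def rxn(rid, name, stoich, lb=0.0, ub=DEFAULT_UPPER, gpr=""):
        return Reaction(id=rid, name=name, stoichiometry=stoich,
                        lower_bound=lb, upper_bound=ub, gpr=gpr)

    m.reactions = [
        # exchanges
        rxn("EX_glc", "glucose exchange", {"glc_e": -1.0}, lb=-spec.glc_uptake),
        rxn("EX_o2", "oxygen exchange", {"o2_e": -1.0}, lb=-spec.o2_uptake),
        rxn("EX_ac", "acetate exchange", {"ac_e": -1.0}),
        rxn("EX_lac", "lactate exchange", {"lac_e": -1.0}),
        rxn("EX_biomass", "biomass drain", {"biomass_e": -1.0}),
        rxn("EX_h2o", "water exchange", {"h2o_e": -1.0}, lb=DEFAULT_LOWER),
        rxn("EX_pi", "phosphate exchange", {"pi_e": -1.0}, lb=DEFAULT_LOWER),
        # transport
        rxn("GLCt", "glucose transport", {"glc_e": -1.0, "glc_c": 1.0}),
        rxn("O2t", "oxygen transport", {"o2_e": -1.0, "o2_c": 1.0}),
        rxn("ACt", "acetate transport", {"ac_c": -1.0, "ac_e": 1.0}),
        rxn("LACt", "lactate transport", {"lac_c": -1.0, "lac_e": 1.0}),
        rxn("BIOt", "biomass boundary transport", {"biomass_c": -1.0, "biomass_e": 1.0}),
        rxn("H2Ot", "water transport", {"h2o_e": -1.0, "h2o_c": 1.0}, lb=DEFAULT_LOWER),
        rxn("PIt", "phosphate transport", {"pi_c": -1.0, "pi_e": 1.0}, lb=DEFAULT_LOWER),
        # internal metabolism
        rxn("GLYC_UP", "upper glycolysis (lumped)",
            {"glc_c": -1.0, "atp_c": -2.0, "dhap_c": 1.0, "g3p_c": 1.0, "adp_c": 2.0}),
        rxn("TPI", "triose-phosphate isomerase",
            {"dhap_c": -1.0, "g3p_c": 1.0}, lb=DEFAULT_LOWER, gpr="tpiA"),
        rxn("GLYC_LO", "lower glycolysis (lumped)",
            {"g3p_c": -1.0, "adp_c": -2.0, "nad_c": -1.0,
             "pyr_c": 1.0, "atp_c": 2.0, "nadh_c": 1.0}),
        rxn("RESP", "respiration (lumped)",
            {"nadh_c": -1.0, "o2_c": -0.5, "adp_c": -spec.po_ratio,
             "nad_c": 1.0, "atp_c": spec.po_ratio}),
        rxn("LDH", "lactate dehydrogenase",
            {"pyr_c": -1.0, "nadh_c": -1.0, "lac_c": 1.0, "nad_c": 1.0}),
        rxn("ACK", "acetate overflow (lumped)",
            {"pyr_c": -1.0, "adp_c": -1.0, "ac_c": 1.0, "atp_c": 1.0}),
        rxn("BIOMASS", "biomass synthesis (lumped)",
            {"pyr_c": -spec.biomass_pyr, "atp_c": -spec.biomass_atp,
             "adp_c": spec.biomass_atp, "biomass_c": 1.0}),
        rxn("ATPM", "ATP maintenance", {"atp_c": -1.0, "adp_c": 1.0},
            lb=spec.maintenance),
    ]
    return m


def build_extended_mini_core(
    spec: MiniCoreSpec | None = None, options: PathwayOptions | None = None
) -> ConstraintModel:
    """Mini-core host with the fuculose pathway grafted on (the usual input
    to the campaign pipeline)."""
    spec = spec or MiniCoreSpec()
    if options is None:
        options = PathwayOptions(lad_uptake_bound=spec.lad_uptake)
    return extend_with_fuculose_pathway(build_mini_core(spec), options)


def build_fuculose_motif(
    glc_bound: float = -2.0, lad_bound: float = -1.0, o2_bound: float = -4.0
) -> ConstraintModel:
    """An 11-reaction reduction of the fuculose scenario for oracle checks.

    Keeps only the decision structure that drives the campaign claims —
    glucose → DHAP, an NADH-producing catabolic/growth lump, respiration as the
    aerobic NADH sink, FucO (LAD → 1,2-PDO) as the anaerobic sink, and the
    lumped aldolase/phosphatase/export step — small enough for
    :func:`fucsim.fba.enumerate_vertices_oracle`.
    """
    m = ConstraintModel(id="fuc_motif", genes=["fucA", "fucO"], objective="EX_bio")
    m.metabolites = [
        _met("glc_e", "glucose"), _met("lad_e", "lactaldehyde"),
        _met("o2_e", "oxygen"), _met("fcl_e", "L-fuculose"),
        _met("pdo_e", "1,2-propanediol"), _met("bio_e", "biomass"),
        _met("dhap_c", "DHAP"), _met("nad_c", "NAD+"), _met("nadh_c", "NADH"),
    ]

    def rxn(rid, stoich, lb=0.0, ub=DEFAULT_UPPER, gpr=""):
        return Reaction(id=rid, stoichiometry=stoich, lower_bound=lb,
                        upper_bound=ub, gpr=gpr)

    m.reactions = [
        rxn("EX_glc", {"glc_e": -1.0}, lb=glc_bound),
        rxn("EX_lad", {"lad_e": -1.0}, lb=lad_bound),
        rxn("EX_o2", {"o2_e": -1.0}, lb=o2_bound),
        rxn("EX_fcl", {"fcl_e": -1.0}),
        rxn("EX_pdo", {"pdo_e": -1.0}),
        rxn("EX_bio", {"bio_e": -1.0}),
        rxn("UP", {"glc_e": -1.0, "dhap_c": 2.0}),
        rxn("CAT", {"dhap_c": -1.0, "nad_c": -1.0, "nadh_c": 1.0, "bio_e": 1.0}),
        rxn("RESP", {"nadh_c": -1.0, "o2_e": -0.5, "nad_c": 1.0}),
        rxn("FUCO", {"lad_e": -1.0, "nadh_c": -1.0, "pdo_e": 1.0, "nad_c": 1.0},
            lb=DEFAULT_LOWER, gpr="fucO"),
        rxn("FCPA", {"dhap_c": -1.0, "lad_e": -1.0, "fcl_e": 1.0}, gpr="fucA"),
    ]
    return m


def random_toy_model(seed: int, n_stages: int = 3) -> tuple[ConstraintModel, float]:
    """A linear-chain LP with a known optimum (the bottleneck capacity).

    Stage capacities are drawn uniformly from {1..10}; stoichiometry is unit;
    the maximum flux through the terminal exchange is exactly
    ``min(capacities)``. Returns ``(model, known_optimum)``.
    """
    if not 1 <= n_stages <= 10:
        raise ValueError("n_stages must be in 1..10")
    rng = np.random.default_rng(seed)
    caps = rng.integers(1, 11, size=n_stages)

    m = ConstraintModel(id=f"toy_{seed}", objective="EX_out")
    m.metabolites = [_met("A_e", "feed")]
    mids = ["A_e"]
    for i in range(1, n_stages):
        mid = f"i{i}_c"
        m.metabolites.append(_met(mid, f"intermediate {i}"))
        mids.append(mid)
    m.metabolites.append(_met("B_e", "product"))
    mids.append("B_e")

    m.reactions = [Reaction(id="EX_in", stoichiometry={"A_e": -1.0},
                            lower_bound=DEFAULT_LOWER, upper_bound=DEFAULT_UPPER)]
    for i in range(n_stages):
        m.reactions.append(
            Reaction(id=f"S{i + 1}", stoichiometry={mids[i]: -1.0, mids[i + 1]: 1.0},
                     lower_bound=0.0, upper_bound=float(caps[i]))
        )
    m.reactions.append(Reaction(id="EX_out", stoichiometry={"B_e": -1.0},
                                lower_bound=0.0, upper_bound=DEFAULT_UPPER))
    return m, float(caps.min())


# ---------------------------------------------------------------------------
# Synthetic fermentation
# ---------------------------------------------------------------------------

@dataclass
class FermentationParams:
    """Generator settings for a shake-flask style batch fermentation.

    Emulates the observed course structure: logistic growth into stationary
    phase by ~24 h, steady glucose draw-down coupled to growth, linear LAD
    depletion completing late in the run, 1,2-PDO accumulating as a fixed
    molar fraction of consumed LAD, and product rising as
    ``yield_param × consumed LAD (mM) × MW_fuculose`` (mg/L). ``sigma`` is
    Gaussian measurement noise on the product in mg/L; the LAD series receives
    the molar-equivalent noise ``sigma / MW_fuculose`` so substrate and
    product uncertainty are commensurate.
    """

    carrying_capacity: float = 5.0  # OD600
    growth_rate: float = 0.25  # 1/h
    initial_od: float = 0.05
    glucose_initial: float = 10.0  # g/L
    lad_initial: float = 5.0  # mM
    lad_depletion_time: float = 84.0  # h, complete consumption
    pdo_fraction: float = 0.8  # mol PDO per mol LAD consumed
    yield_param: float = 0.068  # mol fuculose per mol LAD consumed
    sigma: float = 0.0  # mg/L, product noise
    seed: int = 0
    times: tuple[float, ...] = (0.0, 12.0, 24.0, 36.0, 48.0, 72.0, 96.0)
    fuculose_lod: float = 0.0  # mg/L; present values below this become missing

    def __post_init__(self) -> None:
        if self.carrying_capacity <= 0 or self.growth_rate <= 0:
            raise ValueError("carrying capacity and growth rate must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def simulate_timecourse(params: FermentationParams | None = None) -> TimeCourse:
    """Generate a seeded synthetic fermentation time course.

    Noise-free closed forms (the parameter-recovery oracle): with LAD fully
    consumed from ``lad_initial`` mM, the final product concentration is
    ``yield_param × lad_initial × 164.16`` mg/L, e.g. 55.81 mg/L at yield
    0.068 and 820.8 mg/L at the complete-conversion ceiling (yield 1).
    """
    p = params or FermentationParams()
    rng = np.random.default_rng(p.seed)
    t = np.asarray(p.times, dtype=float)

    K, r, od0 = p.carrying_capacity, p.growth_rate, p.initial_od
    od = K / (1.0 + (K - od0) / od0 * np.exp(-r * t))
    growth_frac = (od - od0) / (K - od0)

    glucose = p.glucose_initial * (1.0 - growth_frac)
    acetate = 2.0 * growth_frac
    lad = p.lad_initial * np.clip(1.0 - t / p.lad_depletion_time, 0.0, 1.0)
    consumed = p.lad_initial - lad  # mM, monotone non-decreasing
    pdo = p.pdo_fraction * consumed
    fuculose = p.yield_param * consumed * MW_FUCULOSE  # mg/L

    if p.sigma > 0:
        fuculose = fuculose + rng.normal(0.0, p.sigma, size=t.shape)
        lad = lad + rng.normal(0.0, p.sigma / MW_FUCULOSE, size=t.shape)
        fuculose = np.clip(fuculose, 0.0, None)
        lad = np.clip(lad, 0.0, None)

    if p.fuculose_lod > 0:
        fuculose = np.where(fuculose < p.fuculose_lod, np.nan, fuculose)

    return TimeCourse(
        time=t, od600=od, glucose=np.clip(glucose, 0.0, None),
        acetate=acetate, lad=lad, pdo=pdo, fuculose=fuculose,
    )
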