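"""A reduced central-metabolism network for an aerobic gammaproteobacterial
methanotroph, packaged as a fully specified, elementally balanced fixture.

The network encodes the canonical methane-oxidation chain (particulate
methane monooxygenase -> PQQ methanol dehydrogenase -> formaldehyde ->
formate -> CO2), the tetrahydromethanopterin and folate formaldehyde
oxidation branches, the RuMP cycle with its Entner-Doudoroff,
Embden-Meyerhof-Parnas and Bifidobacterium-shunt variants, a partial serine
cycle with the malyl-CoA link, the TCA cycle, oxidative phosphorylation with
an explicit periplasmic proton pool, assimilatory nitrate reduction, and a
lumped biomass reaction with growth- and non-growth-associated ATP
maintenance.

Key stoichiometric facts the rest of the package relies on:

* pMMO consumes O2 and CH4 equimolarly and is the sole methane sink, so any
  feasible growth state has an oxygen:methane uptake ratio of at least 1.
* Methanol dehydrogenase feeds electrons to the quinone pool; the NADH
  dehydrogenase is reversible (proton-motive-force-driven reverse electron
  transport), which lets the network balance NADH for pMMO at low oxygen by
  spending ATP, mimicking the mixed respiration/fermentation mode.
* Full combustion of methane caps the oxygen:methane ratio at 2; a
  capacity-limited H2O2-forming NADH oxidase (respiratory overflow) extends
  the feasible band slightly beyond 2, after which no electron acceptor
  capacity remains and growth is infeasible.
* The biomass composition, electron-transport proton stoichiometry and the
  two overflow capacities are calibrated once (the defaults below) so that
  the growth-optimal oxygen:methane uptake ratio falls at ~1.5 and the
  excretion hierarchy switches from acetate-dominated (low ratios) to
  CO2/formate-dominated (high ratios).  These are fixture-level constants,
  not fitted quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import GeneRule, MetabolicModel, Metabolite, Reaction, check_mass_balance

__all__ = [
    "ReducedNetworkConfig",
    "build_reduced_network",
    "load_packaged_network",
    "packaged_network_path",
    "DEFAULT_BIOMASS",
]

BIG = 1000.0

#: biomass precursor draw per gram dry cell weight (mmol gDCW-1); a negative
#: value means the lumped synthesis releases the species.  The mix is more
#: oxidized than whole-cell biomass of a real methanotroph; this is part of
#: the one-time calibration of the fixture's optimal uptake ratio.
DEFAULT_BIOMASS: dict[str, float] = {
    "pyr_c": 4.2,
    "oaa_c": 4.2,
    "akg_c": 1.4,
    "accoa_c": 1.4,
    "nh3_c": 4.8,
    "nadh_c": -25.0,
}


@dataclass
class ReducedNetworkConfig:
    """Tunable constants of the reduced network.

    gam
        Growth-associated ATP maintenance, mmol ATP per gDCW.
    ngam
        Non-growth-associated ATP maintenance, mmol ATP gDCW-1 h-1, applied
        as the lower bound of the ATP maintenance demand.
    protons_per_atp
        Periplasmic protons translocated per ATP by the ATP synthase; the
        NADH dehydrogenase and terminal oxidase each pump four protons, so
        this sets the effective P/O ratio.
    biomass_coefficients
        Precursor draw per gDCW (see :data:`DEFAULT_BIOMASS`).
    ch4_uptake, o2_uptake
        Default medium uptake caps (magnitudes) on the gas exchanges.
    methanol_secretion_cap
        Upper bound on methanol excretion; limits carbon overflow through
        the pre-assimilation branch.
    nadh_oxidase_cap
        Upper bound on the H2O2-forming NADH oxidase, the respiratory
        overflow valve; bounds how far beyond 2:1 the feasible
        oxygen:methane band extends.
    """

    gam: float = 59.8
    ngam: float = 3.5
    protons_per_atp: float = 3.0
    biomass_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIOMASS)
    )
    ch4_uptake: float = 10.0
    o2_uptake: float = 10.0
    methanol_secretion_cap: float = 1.0
    nadh_oxidase_cap: float = 5.0

    def __post_init__(self) -> None:
        if self.gam < 0 or self.ngam < 0:
            raise ValueError("GAM and NGAM must be non-negative")
        if self.protons_per_atp <= 0:
            raise ValueError("protons_per_atp must be positive")


# metabolite id -> (name, formula string, compartment); biomass precursors
# and cofactors use real formulas so every internal reaction balances in
# C, H, O and N.
_METABOLITES: dict[str, tuple[str, str, str]] = {
    # extracellular
    "ch4_e": ("methane", "CH4", "e"),
    "o2_e": ("oxygen", "O2", "e"),
    "co2_e": ("carbon dioxide", "CO2", "e"),
    "for_e": ("formate", "CH2O2", "e"),
    "ac_e": ("acetate", "C2H4O2", "e"),
    "meoh_e": ("methanol", "CH4O", "e"),
    "h2o_e": ("water", "H2O", "e"),
    "no3_e": ("nitrate", "HNO3", "e"),
    "h2o2_e": ("hydrogen peroxide", "H2O2", "e"),
    "h_e": ("periplasmic proton", "H", "e"),
    # cytosol: substrates and small molecules
    "ch4_c": ("methane", "CH4", "c"),
    "o2_c": ("oxygen", "O2", "c"),
    "co2_c": ("carbon dioxide", "CO2", "c"),
    "for_c": ("formate", "CH2O2", "c"),
    "ac_c": ("acetate", "C2H4O2", "c"),
    "meoh_c": ("methanol", "CH4O", "c"),
    "h2o_c": ("water", "H2O", "c"),
    "no3_c": ("nitrate", "HNO3", "c"),
    "h2o2_c": ("hydrogen peroxide", "H2O2", "c"),
    "h_c": ("cytosolic proton", "H", "c"),
    "nh3_c": ("ammonia", "H3N", "c"),
    "fald_c": ("formaldehyde", "CH2O", "c"),
    # cofactors
    "nad_c": ("NAD+", "C21H26N7O14P2", "c"),
    "nadh_c": ("NADH", "C21H28N7O14P2", "c"),
    "q_c": ("ubiquinone-8", "C49H74O4", "c"),
    "qh2_c": ("ubiquinol-8", "C49H76O4", "c"),
    "atp_c": ("ATP", "C10H16N5O13P3", "c"),
    "adp_c": ("ADP", "C10H15N5O10P2", "c"),
    "pi_c": ("orthophosphate", "H3O4P", "c"),
    "coa_c": ("coenzyme A", "C21H36N7O16P3S", "c"),
    "accoa_c": ("acetyl-CoA", "C23H38N7O17P3S", "c"),
    "thf_c": ("tetrahydrofolate", "C19H23N7O6", "c"),
    "mlthf_c": ("5,10-methylene-THF", "C20H23N7O6", "c"),
    "h4mpt_c": ("tetrahydromethanopterin", "C30H45N6O16P", "c"),
    "mlh4mpt_c": ("methylene-H4MPT", "C31H45N6O16P", "c"),
    # sugar phosphates
    "ru5p_c": ("ribulose-5-phosphate", "C5H11O8P", "c"),
    "h6p_c": ("hexulose-6-phosphate", "C6H13O9P", "c"),
    "f6p_c": ("fructose-6-phosphate", "C6H13O9P", "c"),
    "g3p_c": ("glyceraldehyde-3-phosphate", "C3H7O6P", "c"),
    "xu5p_c": ("xylulose-5-phosphate", "C5H11O8P", "c"),
    "r5p_c": ("ribose-5-phosphate", "C5H11O8P", "c"),
    "e4p_c": ("erythrose-4-phosphate", "C4H9O7P", "c"),
    "s7p_c": ("sedoheptulose-7-phosphate", "C7H15O10P", "c"),
    "6pg_c": ("6-phosphogluconate", "C6H13O10P", "c"),
    "kdpg_c": ("2-keto-3-deoxy-6-phosphogluconate", "C6H11O9P", "c"),
    # organic acids and CoA esters
    "pyr_c": ("pyruvate", "C3H4O3", "c"),
    "acp_c": ("acetyl phosphate", "C2H5O5P", "c"),
    "3pg_c": ("3-phosphoglycerate", "C3H7O7P", "c"),
    "glyc_c": ("glycerate", "C3H6O4", "c"),
    "hpyr_c": ("hydroxypyruvate", "C3H4O4", "c"),
    "glx_c": ("glyoxylate", "C2H2O3", "c"),
    "cit_c": ("citrate", "C6H8O7", "c"),
    "akg_c": ("2-oxoglutarate", "C5H6O5", "c"),
    "succ_c": ("succinate", "C4H6O4", "c"),
    "fum_c": ("fumarate", "C4H4O4", "c"),
    "mal_c": ("malate", "C4H6O5", "c"),
    "oaa_c": ("oxaloacetate", "C4H4O5", "c"),
    "malcoa_c": ("malyl-CoA", "C25H40N7O20P3S", "c"),
}


def build_reduced_network(config: ReducedNetworkConfig | None = None) -> MetabolicModel:
    """Build the reduced methanotroph model.

    The returned model is elementally balanced (C, H, O, N) on every
    internal, non-biomass reaction — the build raises if a configuration
    breaks that — carries a synthetic gene rule and a pathway tag on every
    non-exchange reaction, and grows under its default medium.
    """
    cfg = config or ReducedNetworkConfig()
    model = MetabolicModel(model_id="methanotroph_core")
    for mid, (name, formula, comp) in _METABOLITES.items():
        model.add_metabolite(
            Metabolite(mid, name=name, formula=Metabolite.parse_formula(formula), compartment=comp)
        )

    h = cfg.protons_per_atp

    def rxn(rid, stoich, lb, ub, gene="", pathway="", exchange=False, name=""):
        model.add_reaction(
            Reaction(
                id=rid,
                name=name,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gene_rule=GeneRule.from_string(gene),
                pathway=pathway,
                is_exchange=exchange,
            )
        )

    # -- exchanges (negative flux = uptake) ---------------------------------
    rxn("EX_ch4_e", {"ch4_e": -1}, -cfg.ch4_uptake, BIG, exchange=True, name="methane exchange")
    rxn("EX_o2_e", {"o2_e": -1}, -cfg.o2_uptake, BIG, exchange=True, name="oxygen exchange")
    rxn("EX_co2_e", {"co2_e": -1}, 0.0, BIG, exchange=True, name="CO2 exchange")
    rxn("EX_for_e", {"for_e": -1}, 0.0, BIG, exchange=True, name="formate exchange")
    rxn("EX_ac_e", {"ac_e": -1}, 0.0, BIG, exchange=True, name="acetate exchange")
    rxn("EX_meoh_e", {"meoh_e": -1}, 0.0, cfg.methanol_secretion_cap, exchange=True,
        name="methanol exchange")
    rxn("EX_h2o_e", {"h2o_e": -1}, -BIG, BIG, exchange=True, name="water exchange")
    rxn("EX_no3_e", {"no3_e": -1}, -BIG, 0.0, exchange=True, name="nitrate exchange")
    rxn("EX_h2o2_e", {"h2o2_e": -1}, 0.0, BIG, exchange=True, name="peroxide exchange")

    # -- transport ----------------------------------------------------------
    T = "transport"
    rxn("t_ch4_c", {"ch4_e": -1, "ch4_c": 1}, 0, BIG, "g_mtC", T, name="methane diffusion")
    rxn("rxn05468_c", {"o2_e": -1, "o2_c": 1}, 0, BIG, "g_mtO", T,
        name="O2 transport via diffusion")
    rxn("t_co2_c", {"co2_c": -1, "co2_e": 1}, -BIG, BIG, "g_mtD", T, name="CO2 diffusion")
    rxn("t_for_c", {"for_c": -1, "for_e": 1}, 0, BIG, "g_focA", T, name="formate export")
    rxn("t_ac_c", {"ac_c": -1, "ac_e": 1}, 0, BIG, "g_actP", T, name="acetate export")
    rxn("t_meoh_c", {"meoh_c": -1, "meoh_e": 1}, 0, BIG, "g_mtM", T, name="methanol export")
    rxn("t_h2o_c", {"h2o_c": -1, "h2o_e": 1}, -BIG, BIG, "g_aqpZ", T, name="water diffusion")
    rxn("t_no3_c", {"no3_e": -1, "no3_c": 1}, 0, BIG, "g_nrtA", T, name="nitrate import")
    rxn("t_h2o2_c", {"h2o2_c": -1, "h2o2_e": 1}, 0, BIG, "g_mtP", T, name="peroxide export")

    # -- methane oxidation chain -------------------------------------------
    MO = "methane oxidation"
    rxn("pmmo_c",
        {"ch4_c": -1, "o2_c": -1, "nadh_c": -1, "meoh_c": 1, "h2o_c": 1, "nad_c": 1},
        0, BIG, "g_pmoC and g_pmoA and g_pmoB", MO,
        name="particulate methane monooxygenase")
    rxn("mdh_c", {"meoh_c": -1, "q_c": -1, "fald_c": 1, "qh2_c": 1},
        0, BIG, "g_mxaF and g_mxaI", MO, name="methanol dehydrogenase (PQQ)")
    # purposely clamped alternative (NAD-linked) methanol dehydrogenase
    rxn("mdh_alt_c", {"meoh_c": -1, "nad_c": -1, "fald_c": 1, "nadh_c": 1},
        0.0, 0.0, "g_mdh2", MO, name="methanol dehydrogenase (NAD, blocked)")
    rxn("rxn00371_c",
        {"fald_c": -1, "h2o_c": -1, "nad_c": -1, "for_c": 1, "nadh_c": 1},
        0, BIG, "g_fdhA", MO, name="formaldehyde dehydrogenase")
    rxn("fdh_c", {"for_c": -1, "nad_c": -1, "co2_c": 1, "nadh_c": 1},
        0, BIG, "g_fdsA or g_fdsB", MO, name="formate dehydrogenase")

    # -- H4MPT and folate formaldehyde-oxidation branches -------------------
    rxn("h4mpt_lig_c", {"fald_c": -1, "h4mpt_c": -1, "mlh4mpt_c": 1, "h2o_c": 1},
        -BIG, BIG, "g_fae", "H4MPT pathway", name="formaldehyde-H4MPT ligase")
    rxn("h4mpt_ox_c",
        {"mlh4mpt_c": -1, "h2o_c": -2, "nad_c": -1, "h4mpt_c": 1, "for_c": 1, "nadh_c": 1},
        0, BIG, "g_mtdB and g_mch and g_fhcD", "H4MPT pathway",
        name="methylene-H4MPT oxidation to formate")
    rxn("folate_lig_c", {"fald_c": -1, "thf_c": -1, "mlthf_c": 1, "h2o_c": 1},
        -BIG, BIG, "g_folD1", "folate metabolism", name="formaldehyde-THF ligase")
    rxn("folate_ox_c",
        {"mlthf_c": -1, "h2o_c": -2, "nad_c": -1, "thf_c": 1, "for_c": 1, "nadh_c": 1},
        0, BIG, "g_folD2 and g_fhs", "folate metabolism",
        name="methylene-THF oxidation to formate")

    # -- RuMP cycle ---------------------------------------------------------
    RU = "RuMP cycle"
    rxn("hps_c", {"ru5p_c": -1, "fald_c": -1, "h6p_c": 1}, 0, BIG, "g_hxlA", RU,
        name="hexulose-6-phosphate synthase")
    rxn("phi_c", {"h6p_c": -1, "f6p_c": 1}, -BIG, BIG, "g_hxlB", RU,
        name="hexulose-6-phosphate isomerase")
    rxn("rpe_c", {"ru5p_c": -1, "xu5p_c": 1}, -BIG, BIG, "g_rpe", RU,
        name="ribulose-phosphate epimerase")
    rxn("rpi_c", {"ru5p_c": -1, "r5p_c": 1}, -BIG, BIG, "g_rpiA", RU,
        name="ribose-phosphate isomerase")
    rxn("tkt1_c", {"xu5p_c": -1, "r5p_c": -1, "g3p_c": 1, "s7p_c": 1}, -BIG, BIG,
        "g_tktA", RU, name="transketolase I")
    rxn("tal_c", {"g3p_c": -1, "s7p_c": -1, "f6p_c": 1, "e4p_c": 1}, -BIG, BIG,
        "g_talB", RU, name="transaldolase")

    # EMP (FBP) variant
    EMP = "RuMP cycle EMP variant"
    rxn("emp_c", {"f6p_c": -1, "atp_c": -1, "g3p_c": 2, "adp_c": 1}, 0, BIG,
        "g_pfkA and g_fbaA and g_tpiA", EMP,
        name="fructose-6-phosphate to triose phosphates")
    rxn("gapdh_pyk_c",
        {"g3p_c": -1, "nad_c": -1, "adp_c": -2, "pi_c": -1,
         "pyr_c": 1, "nadh_c": 1, "atp_c": 2, "h2o_c": 1},
        0, BIG, "g_gapA and g_pgk and g_eno and g_pykA", EMP,
        name="lower glycolysis (G3P to pyruvate)")

    # EDD (KDPG) variant
    EDD = "RuMP cycle EDD variant"
    rxn("g6pdh_c", {"f6p_c": -1, "nad_c": -1, "h2o_c": -1, "6pg_c": 1, "nadh_c": 1},
        0, BIG, "g_zwf and g_pgl", EDD, name="hexose phosphate oxidation to 6PG")
    rxn("edd_c", {"6pg_c": -1, "kdpg_c": 1, "h2o_c": 1}, 0, BIG, "g_edd", EDD,
        name="6-phosphogluconate dehydratase")
    rxn("eda_c", {"kdpg_c": -1, "pyr_c": 1, "g3p_c": 1}, 0, BIG, "g_eda", EDD,
        name="KDPG aldolase")

    # Bifidobacterium shunt
    BS = "Bifidobacterium shunt"
    rxn("rxn00785_c", {"f6p_c": -1, "g3p_c": -1, "xu5p_c": 1, "e4p_c": 1}, -BIG, BIG,
        "g_tktB", BS, name="F6P + G3P transketolase")
    rxn("rxn01187_c",
        {"xu5p_c": -1, "pi_c": -1, "acp_c": 1, "g3p_c": 1, "h2o_c": 1},
        0, BIG, "g_xfp", BS, name="xylulose-5-phosphate phosphoketolase")

    # -- acetate metabolism -------------------------------------------------
    AC = "acetate metabolism"
    rxn("rxn00230_c", {"acp_c": -1, "adp_c": -1, "ac_c": 1, "atp_c": 1}, -BIG, BIG,
        "g_ackA", AC, name="acetate kinase")
    rxn("rxn00225_c", {"accoa_c": -1, "pi_c": -1, "acp_c": 1, "coa_c": 1}, -BIG, BIG,
        "g_pta", AC, name="phosphotransacetylase")
    rxn("rxn00175_c",
        {"accoa_c": -1, "adp_c": -1, "pi_c": -1, "ac_c": 1, "coa_c": 1, "atp_c": 1},
        0, BIG, "g_acdAB", AC, name="acetate-CoA ligase (ADP-forming)")

    # -- pyruvate node and anaplerosis -------------------------------------
    rxn("rxn05938_c",
        {"pyr_c": -1, "coa_c": -1, "nad_c": -1, "accoa_c": 1, "co2_c": 1, "nadh_c": 1},
        0, BIG, "g_aceE and g_aceF and g_lpd", "pyruvate metabolism",
        name="pyruvate dehydrogenase")
    rxn("pc_c",
        {"pyr_c": -1, "co2_c": -1, "atp_c": -1, "h2o_c": -1,
         "oaa_c": 1, "adp_c": 1, "pi_c": 1},
        0, BIG, "g_pyc", "anaplerosis", name="pyruvate carboxylase")
    rxn("rxn00519_c", {"oaa_c": -1, "pyr_c": 1, "co2_c": 1}, 0, BIG,
        "g_oadA", "anaplerosis", name="oxaloacetate carboxy-lyase")

    # -- TCA cycle ----------------------------------------------------------
    TCA = "TCA cycle"
    rxn("cs_c", {"accoa_c": -1, "oaa_c": -1, "h2o_c": -1, "cit_c": 1, "coa_c": 1},
        0, BIG, "g_gltA", TCA, name="citrate synthase")
    rxn("icd_c", {"cit_c": -1, "nad_c": -1, "akg_c": 1, "co2_c": 1, "nadh_c": 1},
        0, BIG, "g_acnB and g_icd", TCA, name="isocitrate dehydrogenase (lumped)")
    rxn("akgdh_c",
        {"akg_c": -1, "nad_c": -1, "adp_c": -1, "pi_c": -1,
         "succ_c": 1, "co2_c": 1, "nadh_c": 1, "atp_c": 1},
        0, BIG, "g_sucAB and g_sucCD", TCA,
        name="2-oxoglutarate dehydrogenase + succinyl-CoA synthetase")
    rxn("sdh_c", {"succ_c": -1, "q_c": -1, "fum_c": 1, "qh2_c": 1}, -BIG, BIG,
        "g_sdhABCD", TCA, name="succinate dehydrogenase")
    rxn("fum_hydratase_c", {"fum_c": -1, "h2o_c": -1, "mal_c": 1}, -BIG, BIG,
        "g_fumC", TCA, name="fumarate hydratase")
    rxn("mdh_tca_c", {"mal_c": -1, "nad_c": -1, "oaa_c": 1, "nadh_c": 1}, -BIG, BIG,
        "g_mqo", TCA, name="malate dehydrogenase")

    # -- partial serine cycle ----------------------------------------------
    SER = "partial serine cycle"
    rxn("rxn00934_c",
        {"mal_c": -1, "atp_c": -1, "coa_c": -1, "malcoa_c": 1, "adp_c": 1, "pi_c": 1},
        0, BIG, "g_mtkAB", SER, name="malate-CoA ligase")
    rxn("rxn00331_c", {"malcoa_c": -1, "accoa_c": 1, "glx_c": 1}, 0, BIG,
        "g_mclA", SER, name="malyl-CoA lyase")
    rxn("ser_glx_c",
        {"glx_c": -1, "mlthf_c": -1, "h2o_c": -1, "hpyr_c": 1, "thf_c": 1},
        0, BIG, "g_sgaA and g_hprA", SER,
        name="glyoxylate transamination branch (lumped)")
    rxn("rxn01280_c", {"hpyr_c": -1, "nadh_c": -1, "glyc_c": 1, "nad_c": 1},
        0, BIG, "g_gckA", SER, name="hydroxypyruvate reductase (glycerate forming)")
    rxn("glyk_c", {"glyc_c": -1, "atp_c": -1, "3pg_c": 1, "adp_c": 1}, 0, BIG,
        "g_glxK", SER, name="glycerate kinase")
    rxn("pgm_eno_pyk_c", {"3pg_c": -1, "adp_c": -1, "pyr_c": 1, "atp_c": 1, "h2o_c": 1},
        0, BIG, "g_gpmI and g_eno2 and g_pykF", SER,
        name="3PG to pyruvate (lumped)")

    # -- oxidative phosphorylation -----------------------------------------
    OX = "oxidative phosphorylation"
    rxn("rxn10122_c",
        {"nadh_c": -1, "q_c": -1, "h_c": -4, "nad_c": 1, "qh2_c": 1, "h_e": 4},
        -BIG, BIG, "g_nuoA and g_nuoB and g_nuoN", OX,
        name="NADH dehydrogenase (proton pumping, reversible)")
    rxn("cyt_ox_c",
        {"qh2_c": -1, "o2_c": -0.5, "h_c": -4, "q_c": 1, "h2o_c": 1, "h_e": 4},
        0, BIG, "g_cyoABC", OX, name="terminal cytochrome oxidase")
    rxn("rxn10042_c",
        {"adp_c": -1, "pi_c": -1, "h_e": -h, "atp_c": 1, "h2o_c": 1, "h_c": h},
        -BIG, BIG, "g_atpA and g_atpD and g_atpF", OX, name="ATP synthase")
    rxn("nadh_ox_c",
        {"nadh_c": -1, "o2_c": -1, "nad_c": 1, "h2o2_c": 1},
        0, cfg.nadh_oxidase_cap, "g_nox", OX,
        name="NADH oxidase (H2O2 forming, overflow)")

    # -- nitrogen assimilation ---------------------------------------------
    rxn("nas_c",
        {"no3_c": -1, "nadh_c": -4, "nh3_c": 1, "h2o_c": 3, "nad_c": 4},
        0, BIG, "g_nasA and g_nirB", "nitrogen metabolism",
        name="assimilatory nitrate reduction (lumped)")

    # -- maintenance and biomass -------------------------------------------
    rxn("atpm_c", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
        cfg.ngam, BIG, "g_ngam", "maintenance", name="ATP maintenance demand")

    bio: dict[str, float] = {}
    for mid, coeff in cfg.biomass_coefficients.items():
        bio[mid] = bio.get(mid, 0.0) - coeff
    # CoA moiety of the acetyl-CoA draw is returned to the pool
    accoa_draw = cfg.biomass_coefficients.get("accoa_c", 0.0)
    if accoa_draw:
        bio["coa_c"] = bio.get("coa_c", 0.0) + accoa_draw
    # NADH release/draw balances its NAD counterpart
    nadh = cfg.biomass_coefficients.get("nadh_c", 0.0)
    if nadh:
        bio["nad_c"] = bio.get("nad_c", 0.0) + nadh
    bio["atp_c"] = bio.get("atp_c", 0.0) - cfg.gam
    bio["h2o_c"] = bio.get("h2o_c", 0.0) - cfg.gam
    bio["adp_c"] = bio.get("adp_c", 0.0) + cfg.gam
    bio["pi_c"] = bio.get("pi_c", 0.0) + cfg.gam
    rxn("biomass_c", bio, 0, BIG, "g_bio", "biomass", name="biomass production")

    model.objective_reaction_id = "biomass_c"
    model.validate()

    report = check_mass_balance(model)
    if not report.balanced:
        raise ValueError(
            f"reduced network configuration is elementally imbalanced: "
            f"{report.imbalances[:5]}"
        )
    return model


def packaged_network_path():
    """Path of the versioned reduced-network JSON shipped with the package."""
    from importlib.resources import files

    return files("methanoflux.data") / "methanotroph_core.json"


def load_packaged_network() -> MetabolicModel:
    """Read the packaged reduced-network fixture file.

    Equivalent to :func:`build_reduced_network` with default configuration;
    the file exists so the model can be consumed as data (CLI, external
    tools) without running the builder.
    """
    from .io import read_model

    return read_model(str(packaged_network_path()), format="json")
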