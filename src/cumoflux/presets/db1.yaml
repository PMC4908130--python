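# DB-1 melanoma perfused-bioreactor network: glycolysis, oxidative and
# non-oxidative pentose phosphate pathway, TCA cycle with anaplerosis at
# pyruvate carboxylase and at the succinyl-CoA level, glutaminolysis,
# malate-aspartate shuttle exchange, mitochondrial/cytosolic malic enzymes,
# de novo fatty-acid synthesis (two-pool acyl chain), and Michaelis-Menten
# lactate transport.  Fluxes in mmol/L-cell/h; pools in mM per liter-cell.
# Pool sizes other than glutamate (9.2 mM, fitted) and total cellular
# lactate (16 mM, a fitted parameter set to the value consistent with the
# lactate transport kinetics at the operating medium level) are not
# printed in the source study and are literature-plausible defaults for
# proliferating tumor cells; intermediates are kept small (fast
# turnover).  Medium lactate starts at its perfusion steady level: the
# label switch happens on a running reactor.

compartments: [medium, cytosol, mitochondrion]

pools:
  # medium (GLC_e/GLN_e clamped by the perfusion controller; LAC_e accumulates)
  - {name: GLC_e, compartment: medium, n_carbons: 6, pool_size: 26.0}
  - {name: GLN_e, compartment: medium, n_carbons: 5, pool_size: 2.0}
  - {name: LAC_e, compartment: medium, n_carbons: 3, pool_size: 6.25}
  # cytosol
  - {name: GLC_c, compartment: cytosol, n_carbons: 6, pool_size: 1.0}
  - {name: G6P,   compartment: cytosol, n_carbons: 6, pool_size: 0.2}
  - {name: F6P,   compartment: cytosol, n_carbons: 6, pool_size: 0.1}
  - {name: GAP,   compartment: cytosol, n_carbons: 3, pool_size: 0.1}
  - {name: P5P,   compartment: cytosol, n_carbons: 5, pool_size: 0.1}
  - {name: S7P,   compartment: cytosol, n_carbons: 7, pool_size: 0.05}
  - {name: E4P,   compartment: cytosol, n_carbons: 4, pool_size: 0.02}
  - {name: PYR_c, compartment: cytosol, n_carbons: 3, pool_size: 0.5}
  - {name: LAC_c, compartment: cytosol, n_carbons: 3, pool_size: 16.0}
  - {name: GLN_c, compartment: cytosol, n_carbons: 5, pool_size: 2.0}
  - {name: GLU,   compartment: cytosol, n_carbons: 5, pool_size: 9.2}
  - {name: ASP,   compartment: cytosol, n_carbons: 4, pool_size: 2.0}
  - {name: ACoA_c, compartment: cytosol, n_carbons: 2, pool_size: 0.05}
  - {name: MAL_c, compartment: cytosol, n_carbons: 4, pool_size: 0.5}
  - {name: FA_c,  compartment: cytosol, n_carbons: 2, pool_size: 18.0}
  - {name: FA_m,  compartment: cytosol, n_carbons: 2, pool_size: 180.0}
  # mitochondrion
  - {name: PYR_m, compartment: mitochondrion, n_carbons: 3, pool_size: 0.2}
  - {name: ACoA_m, compartment: mitochondrion, n_carbons: 2, pool_size: 0.05}
  # citrate is branched: central carbon 3 bonds to 2, 4 and the 6-carboxyl
  - {name: CIT,   compartment: mitochondrion, n_carbons: 6, pool_size: 0.5,
     bonds: [[1, 2], [2, 3], [3, 6], [3, 4], [4, 5]]}
  - {name: AKG,   compartment: mitochondrion, n_carbons: 5, pool_size: 0.5}
  # succinate/fumarate lump with 2-fold rotational symmetry
  - {name: SUC,   compartment: mitochondrion, n_carbons: 4, pool_size: 0.5,
     symmetric: true, symmetry_map: [4, 3, 2, 1]}
  - {name: MAL_m, compartment: mitochondrion, n_carbons: 4, pool_size: 0.5}
  - {name: OAA_m, compartment: mitochondrion, n_carbons: 4, pool_size: 0.05}

sources:
  - {name: AA_GLUCO, n_carbons: 3}   # glucogenic amino acids -> pyruvate (unlabeled)
  - {name: AA_KETO,  n_carbons: 2}   # ketogenic AA / FA -> acetyl-CoA (unlabeled)
  - {name: SRC_ANA,  n_carbons: 4}   # anaplerotic source at the SucCoA level
  - {name: CO2_in,   n_carbons: 1}   # carboxylation CO2 (unlabeled)

sinks: [CO2, SINK]

reactions:
  # glycolysis (EMP), lumped below the committed steps
  - {name: HK,     stoich: "GLC_c -> G6P",          atoms: "abcdef -> abcdef"}
  - {name: PGI,    stoich: "G6P -> F6P",            atoms: "abcdef -> abcdef"}
  # aldolase + TPI: C1-C3 via DHAP (reversed), C4-C6 directly
  - {name: ALD,    stoich: "F6P -> GAP + GAP",      atoms: "abcdef -> cba + def"}
  - {name: GLY,    stoich: "GAP -> PYR_c",          atoms: "abc -> abc"}
  # pentose phosphate pathway (classical F-type)
  - {name: PPP_OX, stoich: "G6P -> P5P + CO2",      atoms: "abcdef -> bcdef + a",
     flux_role: fixed}
  - {name: TK1,    stoich: "P5P + P5P -> S7P + GAP",
     atoms: "abcde + fghij -> abfghij + cde", reversible: true}
  - {name: TA,     stoich: "S7P + GAP -> F6P + E4P",
     atoms: "abcdefg + hij -> abchij + defg", reversible: true}
  - {name: TK2,    stoich: "P5P + E4P -> F6P + GAP",
     atoms: "abcde + fghi -> abfghi + cde", reversible: true}
  # pyruvate branches
  - {name: LDH,    stoich: "PYR_c -> LAC_c",        atoms: "abc -> abc",
     flux_role: fixed}
  - {name: GAA,    stoich: "AA_GLUCO -> PYR_c",     atoms: "abc -> abc",
     flux_role: fixed}
  - {name: MPC,    stoich: "PYR_c -> PYR_m",        atoms: "abc -> abc"}
  # TCA cycle
  - {name: PDH,    stoich: "PYR_m -> ACoA_m + CO2", atoms: "abc -> bc + a"}
  - {name: PC,     stoich: "PYR_m + CO2_in -> OAA_m", atoms: "abc + d -> abcd",
     flux_role: free}
  - {name: KAA,    stoich: "AA_KETO -> ACoA_m",     atoms: "ab -> ab",
     flux_role: fixed}
  - {name: CS,     stoich: "ACoA_m + OAA_m -> CIT", atoms: "ab + cdef -> fedbac"}
  - {name: IDH,    stoich: "CIT -> AKG + CO2",      atoms: "abcdef -> abcde + f",
     flux_role: free}
  - {name: AKGDH,  stoich: "AKG -> SUC + CO2",      atoms: "abcde -> bcde + a"}
  - {name: SDHFUM, stoich: "SUC -> MAL_m",          atoms: "abcd -> abcd"}
  - {name: MDH_m,  stoich: "MAL_m -> OAA_m",        atoms: "abcd -> abcd"}
  # anaplerosis at the succinyl-CoA level (net + exchange with unlabeled pool)
  - {name: ANA,    stoich: "SRC_ANA -> SUC",        atoms: "abcd -> abcd",
     reversible: true, flux_role: free}
  # glutamine / glutamate
  - {name: GLS,    stoich: "GLN_c -> GLU",          atoms: "abcde -> abcde",
     flux_role: free}
  - {name: GLUX,   stoich: "GLU -> AKG",            atoms: "abcde -> abcde",
     reversible: true}
  # malate-aspartate shuttle leg and aspartate efflux
  - {name: GOT,    stoich: "OAA_m -> ASP",          atoms: "abcd -> abcd",
     reversible: true}
  - {name: ASP_EFF, stoich: "ASP -> SINK",          atoms: "abcd -> abcd",
     flux_role: free}
  # malic enzymes
  - {name: ME2,    stoich: "MAL_m -> PYR_m + CO2",  atoms: "abcd -> abc + d",
     flux_role: free}
  - {name: ME1,    stoich: "MAL_c -> PYR_c + CO2",  atoms: "abcd -> abc + d"}
  # citrate export to lipogenesis (ATP-citrate lyase + cytosolic MDH lumped)
  - {name: CITLY,  stoich: "CIT -> ACoA_c + MAL_c", atoms: "abcdef -> ed + fcba"}
  # fatty-acid synthesis in acetyl units; precursor and membrane acyl pools
  - {name: FAS,    stoich: "ACoA_c -> FA_c",        atoms: "ab -> ab",
     flux_role: free}
  - {name: FAT,    stoich: "FA_c -> FA_m",          atoms: "ab -> ab"}
  - {name: FAD,    stoich: "FA_m -> SINK",          atoms: "ab -> ab"}

transports:
  - {name: T_GLC, out: GLC_e, in: GLC_c, kinetics: balancing}
  - {name: T_GLN, out: GLN_e, in: GLN_c, kinetics: balancing}
  - {name: T_LAC, out: LAC_e, in: LAC_c, kinetics: michaelis-menten,
     jmax: 395.0, km: 3.5}
  - {name: T_MAL, out: MAL_c, in: MAL_m, kinetics: balancing}

perfusion:
  cell_volume_ml: 1.0        # 5e8 cells == 1 mL cell volume
  medium_volume_ml: 120.0
  feed_rate_ml_h: 24.0
  clamped: [GLC_e, GLN_e]
  feed_composition:
    GLC_e:
      concentration: 26.0
      label: [{fraction: 1.0, positions: [1, 6]}]   # [1,6-13C2]glucose
    GLN_e:
      concentration: 2.0
      label: []                                     # unlabeled glutamine

metadata:
  description: DB-1 melanoma bioreactor preset (hyperglycemia, normoxia)
  reported:
    MRO2_calculated: 32.0
    MRO2_experimental: [33.0, 36.0]     # text vs table value
    MRglc_experimental: [90.0, 91.0]    # text vs table value
    CMRlac_calculated: 150.0
    glutamate_pool_mM: 9.2
    warburg_parameter: 21.0
    F_atpOx: 154.0
    F_atpCyt: 150.0
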