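# Default allometric equation registry.
#
# LN_LN entries are the generalized national ln-ln aboveground-biomass
# equations by species group (biomass_kg = exp(b0 + b1 * ln(dbh_cm))),
# coefficients transcribed from the published national compilation
# (Jenkins et al. 2003, Table 4).  The r_squared / n_obs metadata are
# nominal (representative of the published pseudodata fits, not transcribed
# at printed precision) and feed only the error-simulation engine.
#
# VOLUME_CRM and SPECIES_SPECIFIC entries are GENERIC DEMONSTRATIVE
# DEFAULTS: the regional volume/ratio coefficient sets and local species
# equations are not printed in any source packaged here.  Replace them with
# a regional registry file for real analyses.  CRM volume is the
# combined-variable form v_m3 = a + b * dbh_cm^2 * bole_height_m; density
# is green-wood-free dry density in kg/m3; bole_to_total_ratio expands bole
# biomass to whole-tree.

equations:
  # ---- LN_LN: hardwood groups -------------------------------------------
  - {family: LN_LN, group: aspen_alder_cottonwood_willow,
     coefficients: {b0: -2.2094, b1: 2.3867},
     r_squared: 0.953, n_obs: 230, dbh_range: [2.5, 70.0],
     source: national generalized ln-ln compilation}
  - {family: LN_LN, group: soft_maple_birch,
     coefficients: {b0: -1.9123, b1: 2.3651},
     r_squared: 0.958, n_obs: 316, dbh_range: [2.5, 66.0],
     source: national generalized ln-ln compilation}
  - {family: LN_LN, group: mixed_hardwood,
     coefficients: {b0: -2.4800, b1: 2.4835},
     r_squared: 0.980, n_obs: 289, dbh_range: [2.5, 56.0],
     source: national generalized ln-ln compilation}
  - {family: LN_LN, group: hard_maple_oak_hickory_beech,
     coefficients: {b0: -2.0127, b1: 2.4342},
     r_squared: 0.988, n_obs: 485, dbh_range: [2.5, 73.0],
     source: national generalized ln-ln compilation}
  # ---- LN_LN: softwood groups -------------------------------------------
  - {family: LN_LN, group: cedar_larch,
     coefficients: {b0: -2.0336, b1: 2.2592},
     r_squared: 0.981, n_obs: 196, dbh_range: [2.5, 250.0],
     source: national generalized ln-ln compilation}
  - {family: LN_LN, group: douglas_fir,
     coefficients: {b0: -2.2304, b1: 2.4435},
     r_squared: 0.992, n_obs: 165, dbh_range: [2.5, 210.0],
     source: national generalized ln-ln compilation}
  - {family: LN_LN, group: true_fir_hemlock,
     coefficients: {b0: -2.5384, b1: 2.4814},
     r_squared: 0.992, n_obs: 395, dbh_range: [2.5, 230.0],
     source: national generalized ln-ln compilation}
  - {family: LN_LN, group: pine,
     coefficients: {b0: -2.5356, b1: 2.4349},
     r_squared: 0.987, n_obs: 331, dbh_range: [2.5, 180.0],
     source: national generalized ln-ln compilation}
  - {family: LN_LN, group: spruce,
     coefficients: {b0: -2.0773, b1: 2.3323},
     r_squared: 0.988, n_obs: 212, dbh_range: [2.5, 250.0],
     source: national generalized ln-ln compilation}
  # ---- LN_LN: woodland group --------------------------------------------
  - {family: LN_LN, group: juniper_oak_mesquite,
     coefficients: {b0: -0.7152, b1: 1.7029},
     r_squared: 0.938, n_obs: 61, dbh_range: [2.5, 78.0],
     source: national generalized ln-ln compilation}

  # ---- VOLUME_CRM: generic demonstrative defaults -----------------------
  - {family: VOLUME_CRM, group: mixed_hardwood,
     coefficients: {a: 0.002, b: 3.4e-05, density: 600.0,
                    bole_to_total_ratio: 0.78},
     r_squared: 0.96, n_obs: 150, dbh_range: [2.5, 90.0],
     source: generic combined-variable default (replace regionally)}
  - {family: VOLUME_CRM, group: hard_maple_oak_hickory_beech,
     coefficients: {a: 0.002, b: 3.5e-05, density: 640.0,
                    bole_to_total_ratio: 0.76},
     r_squared: 0.96, n_obs: 150, dbh_range: [2.5, 90.0],
     source: generic combined-variable default (replace regionally)}
  - {family: VOLUME_CRM, group: soft_maple_birch,
     coefficients: {a: 0.002, b: 3.4e-05, density: 540.0,
                    bole_to_total_ratio: 0.78},
     r_squared: 0.96, n_obs: 150, dbh_range: [2.5, 90.0],
     source: generic combined-variable default (replace regionally)}
  - {family: VOLUME_CRM, group: aspen_alder_cottonwood_willow,
     coefficients: {a: 0.002, b: 3.3e-05, density: 420.0,
                    bole_to_total_ratio: 0.80},
     r_squared: 0.96, n_obs: 150, dbh_range: [2.5, 90.0],
     source: generic combined-variable default (replace regionally)}
  - {family: VOLUME_CRM, group: pine,
     coefficients: {a: 0.002, b: 3.3e-05, density: 470.0,
                    bole_to_total_ratio: 0.82},
     r_squared: 0.96, n_obs: 150, dbh_range: [2.5, 90.0],
     source: generic combined-variable default (replace regionally)}
  - {family: VOLUME_CRM, group: true_fir_hemlock,
     coefficients: {a: 0.002, b: 3.3e-05, density: 420.0,
                    bole_to_total_ratio: 0.82},
     r_squared: 0.96, n_obs: 150, dbh_range: [2.5, 90.0],
     source: generic combined-variable default (replace regionally)}
  - {family: VOLUME_CRM, group: cedar_larch,
     coefficients: {a: 0.002, b: 3.3e-05, density: 440.0,
                    bole_to_total_ratio: 0.82},
     r_squared: 0.96, n_obs: 150, dbh_range: [2.5, 90.0],
     source: generic combined-variable default (replace regionally)}
  - {family: VOLUME_CRM, group: douglas_fir,
     coefficients: {a: 0.002, b: 3.4e-05, density: 480.0,
                    bole_to_total_ratio: 0.82},
     r_squared: 0.96, n_obs: 150, dbh_range: [2.5, 90.0],
     source: generic combined-variable default (replace regionally)}
  - {family: VOLUME_CRM, group: spruce,
     coefficients: {a: 0.002, b: 3.3e-05, density: 400.0,
                    bole_to_total_ratio: 0.82},
     r_squared: 0.96, n_obs: 150, dbh_range: [2.5, 90.0],
     source: generic combined-variable default (replace regionally)}
  - {family: VOLUME_CRM, group: juniper_oak_mesquite,
     coefficients: {a: 0.002, b: 3.3e-05, density: 550.0,
                    bole_to_total_ratio: 0.72},
     r_squared: 0.96, n_obs: 150, dbh_range: [2.5, 90.0],
     source: generic combined-variable default (replace regionally)}

  # ---- SPECIES_SPECIFIC: generic demonstrative defaults -----------------
  - {family: SPECIES_SPECIFIC, group: red_maple,
     coefficients: {b0: -1.8900, b1: 2.3200},
     r_squared: 0.97, n_obs: 60, dbh_range: [2.5, 60.0],
     source: generic local ln-ln default (replace regionally)}
  - {family: SPECIES_SPECIFIC, group: yellow_poplar,
     coefficients: {b0: -2.4000, b1: 2.4500},
     r_squared: 0.97, n_obs: 55, dbh_range: [2.5, 70.0],
     source: generic local ln-ln default (replace regionally)}
  - {family: SPECIES_SPECIFIC, group: white_oak,
     coefficients: {b0: -1.9500, b1: 2.4700},
     r_squared: 0.98, n_obs: 70, dbh_range: [2.5, 80.0],
     source: generic local ln-ln default (replace regionally)}
  - {family: SPECIES_SPECIFIC, group: loblolly_pine,
     coefficients: {b0: -2.4900, b1: 2.4600},
     r_squared: 0.98, n_obs: 80, dbh_range: [2.5, 70.0],
     source: generic local ln-ln default (replace regionally)}

species_to_group:
  red_maple: soft_maple_birch
  sugar_maple: hard_maple_oak_hickory_beech
  yellow_poplar: mixed_hardwood
  sweetgum: mixed_hardwood
  black_gum: mixed_hardwood
  white_oak: hard_maple_oak_hickory_beech
  northern_red_oak: hard_maple_oak_hickory_beech
  chestnut_oak: hard_maple_oak_hickory_beech
  pignut_hickory: hard_maple_oak_hickory_beech
  american_beech: hard_maple_oak_hickory_beech
  loblolly_pine: pine
  virginia_pine: pine
  eastern_white_pine: pine
  eastern_hemlock: true_fir_hemlock
  eastern_redcedar: cedar_larch
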