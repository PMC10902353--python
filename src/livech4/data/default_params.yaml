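# Default parameter registry for the livestock methane inventory.
#
# All values are national defaults in the spirit of the 2019 IPCC refinement
# and Chinese provincial inventory guidelines; they are deliberately
# overridable via a user config (same layout) and region/year trait tables.
#
# Units are stated per field.  Percentages are on the 0-100 scale.

regions: [default]

coefficients:
  # NE_m = cf * W^0.75               [MJ day-1], cf keyed by category
  cf_maintenance:
    dairy_cattle: 0.386
    nondairy_cattle: 0.322
    buffalo: 0.322
    sheep: 0.217
    goat: 0.217
    swine: 0.197
  # NE_a = ca * NE_m, ca keyed by feeding situation (dimensionless)
  ca_activity:
    stall: 0.0
    pasture: 0.17
    grazing_large_area: 0.36
  # NE_p = cp * NE_m * pregnancy_fraction (dimensionless)
  cp_pregnancy: 0.10
  # NE_g = 22.02 * (W / (growth_c * mature_weight))^0.75 * WG^1.097
  growth_c: 0.8
  # Energy value of wool [MJ kg-1]
  ev_wool: 24.0
  # Energy content of methane [MJ kg-1]
  methane_energy_mj_per_kg: 55.65

# Whether the "other" subclass of sheep/goats accrues growth energy
# (treats it as partly lambs/kids).  Off by default.
sheep_other_growth: false

manure_constants:
  # Methane density used to convert m3 CH4 to kg [kg m-3].  The literal
  # guideline constant 0.067 can be substituted here for literal mode.
  methane_density_kg_per_m3: 0.67

# Tier 2 animal traits, keyed category -> subclass.
# body_weight kg; weight_gain kg day-1; milk_yield kg head-1 yr-1;
# milk_fat % by mass; wool_yield kg head-1 yr-1; pregnancy_fraction 0-1;
# DE % of gross energy digestible; Ym % of gross energy emitted as methane.
traits:
  dairy_cattle:
    mature_female:
      body_weight: 550
      milk_yield: 6000
      milk_fat: 3.5
      pregnancy_fraction: 0.8
      DE: 65
      Ym: 6.5
      feeding_situation: stall
    young:
      body_weight: 220
      weight_gain: 0.5
      mature_weight: 550
      DE: 65
      Ym: 5.5
      feeding_situation: stall
    other:
      body_weight: 450
      DE: 65
      Ym: 6.5
      feeding_situation: stall
  nondairy_cattle:
    mature_female:
      body_weight: 400
      pregnancy_fraction: 0.5
      DE: 60
      Ym: 6.5
      feeding_situation: pasture
    young:
      body_weight: 210
      weight_gain: 0.5
      mature_weight: 400
      DE: 60
      Ym: 5.5
      feeding_situation: pasture
    other:
      body_weight: 420
      DE: 60
      Ym: 6.5
      feeding_situation: pasture
  buffalo:
    mature_female:
      body_weight: 500
      pregnancy_fraction: 0.5
      DE: 55
      Ym: 6.5
      feeding_situation: pasture
    young:
      body_weight: 200
      weight_gain: 0.35
      mature_weight: 500
      DE: 55
      Ym: 5.5
      feeding_situation: pasture
    other:
      body_weight: 550
      DE: 55
      Ym: 6.5
      feeding_situation: pasture
  sheep:
    mature_female:
      body_weight: 45
      pregnancy_fraction: 0.7
      wool_yield: 1.5
      DE: 60
      Ym: 6.5
      feeding_situation: grazing_large_area
    other:
      body_weight: 35
      wool_yield: 1.0
      DE: 60
      Ym: 5.5
      feeding_situation: grazing_large_area
  goat:
    mature_female:
      body_weight: 40
      pregnancy_fraction: 0.7
      wool_yield: 0.4
      DE: 60
      Ym: 6.5
      feeding_situation: grazing_large_area
    other:
      body_weight: 30
      wool_yield: 0.3
      DE: 60
      Ym: 5.5
      feeding_situation: grazing_large_area
  swine:
    whole_herd:
      body_weight: 80
      DE: 70
      Ym: 1.2
      feeding_situation: stall

# Manure parameters, keyed by Tier 2 category.
# vs_rate: kg VS per 1000 kg animal mass per day; b0: m3 CH4 per kg VS;
# system_fractions: share of manure handled per management system (sums to 1).
manure:
  dairy_cattle:
    vs_rate: 9.6
    b0: 0.24
    system_fractions:
      liquid_slurry: 0.20
      solid_storage: 0.45
      daily_spread: 0.10
      pasture: 0.10
      anaerobic_digester: 0.15
  nondairy_cattle:
    vs_rate: 8.2
    b0: 0.18
    system_fractions:
      solid_storage: 0.50
      dry_lot: 0.20
      pasture: 0.25
      anaerobic_digester: 0.05
  buffalo:
    vs_rate: 13.5
    b0: 0.10
    system_fractions:
      solid_storage: 0.50
      pasture: 0.40
      daily_spread: 0.10
  sheep:
    vs_rate: 8.2
    b0: 0.19
    system_fractions:
      pasture: 0.70
      solid_storage: 0.30
  goat:
    vs_rate: 9.0
    b0: 0.18
    system_fractions:
      pasture: 0.70
      solid_storage: 0.30
  swine:
    vs_rate: 5.4
    b0: 0.45
    system_fractions:
      liquid_slurry: 0.40
      solid_storage: 0.25
      lagoon: 0.10
      anaerobic_digester: 0.25

# Methane conversion factors [% of B0] by management system and climate class.
# Values increase cool -> temperate -> warm for every system.
mcf:
  pasture: {cool: 1.0, temperate: 1.5, warm: 2.0}
  daily_spread: {cool: 0.1, temperate: 0.5, warm: 1.0}
  solid_storage: {cool: 2.0, temperate: 4.0, warm: 5.0}
  dry_lot: {cool: 1.0, temperate: 1.5, warm: 2.0}
  liquid_slurry: {cool: 17.0, temperate: 35.0, warm: 55.0}
  anaerobic_digester: {cool: 1.0, temperate: 2.0, warm: 3.0}
  lagoon: {cool: 60.0, temperate: 73.0, warm: 80.0}
  other: {cool: 5.0, temperate: 10.0, warm: 15.0}

# Fixed EFs for Tier 1 categories [kg CH4 head-1 yr-1].
tier1_efs:
  horse: {enteric: 18.0, manure: 1.64}
  donkey: {enteric: 10.0, manure: 0.90}
  mule: {enteric: 10.0, manure: 0.90}
  camel: {enteric: 46.0, manure: 1.92}
  poultry: {enteric: 0.02, manure: 0.02}
  rabbit: {enteric: 0.25, manure: 0.08}

# Average lifespan within a calendar year [months], by population type.
# Slaughtered animals emit only until death, assumed uniform over the year.
lifespans:
  dairy_cattle: {stock: 12.0, slaughtered: 6.0}
  nondairy_cattle: {stock: 12.0, slaughtered: 6.0}
  buffalo: {stock: 12.0, slaughtered: 6.0}
  sheep: {stock: 5.6, slaughtered: 3.0}
  goat: {stock: 5.6, slaughtered: 3.0}
  camel: {stock: 12.0, slaughtered: 6.0}
  swine: {stock: 10.0, slaughtered: 6.0}
  horse: {stock: 12.0, slaughtered: 6.0}
  donkey: {stock: 12.0, slaughtered: 6.0}
  mule: {stock: 12.0, slaughtered: 6.0}
  poultry: {stock: 10.0, slaughtered: 2.0}
  rabbit: {stock: 8.0, slaughtered: 2.0}

# Coefficients of variation used by the Monte Carlo sampler.
# ef: std/mean of the normal EF perturbation; activity: CV of the uniform
# activity-data perturbation.
cvs:
  dairy_cattle: {ef: 0.20, activity: 0.10}
  nondairy_cattle: {ef: 0.20, activity: 0.10}
  buffalo: {ef: 0.20, activity: 0.10}
  sheep: {ef: 0.20, activity: 0.10}
  goat: {ef: 0.20, activity: 0.10}
  camel: {ef: 0.25, activity: 0.15}
  swine: {ef: 0.20, activity: 0.10}
  horse: {ef: 0.25, activity: 0.15}
  donkey: {ef: 0.25, activity: 0.15}
  mule: {ef: 0.25, activity: 0.15}
  poultry: {ef: 0.25, activity: 0.15}
  rabbit: {ef: 0.25, activity: 0.15}

# Shares used to split whole-herd counts of Tier 2 categories into
# subclasses.  Each map sums to 1.
subclass_shares:
  dairy_cattle: {mature_female: 0.50, young: 0.25, other: 0.25}
  nondairy_cattle: {mature_female: 0.45, young: 0.30, other: 0.25}
  buffalo: {mature_female: 0.45, young: 0.30, other: 0.25}
  sheep: {mature_female: 0.60, other: 0.40}
  goat: {mature_female: 0.60, other: 0.40}
  swine: {whole_herd: 1.0}

# Carcass weights [kg head-1] used when reconstructing slaughtered head
# counts from meat production.
carcass_weights:
  nondairy_cattle: 150.0
  buffalo: 160.0
  sheep: 20.0
  goat: 18.0
  swine: 77.0
  poultry: 1.5
  rabbit: 1.2
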