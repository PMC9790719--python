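# Default receptor roster and food-web diet matrix for the evaluative region.
# Masses kg, feeding rates kg food/kg body/day, water ingestion L/kg/day,
# ventilation L water/kg/h (water-respirers) or m^3 air/kg/h (air-breathers),
# rate constants 1/h, population biomass kg in the 100 000 km^2 region.
params:
  egestion_factor: 0.25      # fecal egestion as fraction of dietary clearance
  urinary_clearance: 0.0012  # L/kg/h, air-breathers only
  gut_ed_a: 3.0e-7           # gut absorption efficiency E_D = 1/(a*KOW + b)
  gut_ed_b: 2.0
  resp_eff_water: 0.8        # gill uptake efficiency
  resp_eff_air: 0.7          # lung uptake efficiency
  body_water_fraction: 0.7   # non-lipid contribution to body-water partition
  body_density: 1000.0       # kg/m^3

receptors:
  - receptor_id: foliage
    taxon_class: autotroph
    habitat: agricultural
    media_source: foliage
    population_biomass: 5.0e10
  - receptor_id: root_crop
    taxon_class: autotroph
    habitat: agricultural
    media_source: root_crop
    population_biomass: 2.0e9
  - receptor_id: aquatic_invertebrate
    taxon_class: aquatic_invertebrate
    habitat: aquatic
    respiration_medium: water
    body_mass: 1.0e-4
    lipid_fraction: 0.02
    ventilation_rate: 300.0
    feeding_rate: 0.0
    diet: {}
    growth_rate_constant: 2.0e-4
    population_biomass: 1.0e8
  - receptor_id: planktivorous_fish
    taxon_class: fish
    habitat: aquatic
    respiration_medium: water
    body_mass: 0.05
    lipid_fraction: 0.05
    ventilation_rate: 150.0
    feeding_rate: 0.03
    water_ingestion: 0.0
    diet: {aquatic_invertebrate: 1.0}
    growth_rate_constant: 5.0e-5
    population_biomass: 1.0e7
  - receptor_id: piscivorous_fish
    taxon_class: fish
    habitat: aquatic
    respiration_medium: water
    body_mass: 2.0
    lipid_fraction: 0.08
    ventilation_rate: 90.0
    feeding_rate: 0.02
    diet: {planktivorous_fish: 1.0}
    growth_rate_constant: 2.0e-5
    population_biomass: 1.0e6
  - receptor_id: aquatic_bird
    taxon_class: bird
    habitat: aquatic
    respiration_medium: air
    body_mass: 1.2
    lipid_fraction: 0.06
    ventilation_rate: 0.06
    feeding_rate: 0.2
    water_ingestion: 0.05
    diet: {planktivorous_fish: 1.0}
    growth_rate_constant: 2.0e-5
    population_biomass: 1.0e5
  - receptor_id: small_rodent
    taxon_class: mammal
    habitat: terrestrial
    respiration_medium: air
    body_mass: 0.03
    lipid_fraction: 0.05
    ventilation_rate: 0.08
    feeding_rate: 0.15
    water_ingestion: 0.15
    diet: {foliage: 0.95, soil: 0.05}
    growth_rate_constant: 1.0e-4
    population_biomass: 1.0e7
  - receptor_id: terrestrial_carnivore
    taxon_class: mammal
    habitat: terrestrial
    respiration_medium: air
    body_mass: 5.0
    lipid_fraction: 0.07
    ventilation_rate: 0.03
    feeding_rate: 0.05
    water_ingestion: 0.08
    diet: {small_rodent: 1.0}
    growth_rate_constant: 1.0e-5
    population_biomass: 1.0e5
  - receptor_id: dairy_cow
    taxon_class: mammal
    habitat: agricultural
    respiration_medium: air
    body_mass: 600.0
    lipid_fraction: 0.2
    ventilation_rate: 0.012
    feeding_rate: 0.1
    water_ingestion: 0.1
    diet: {foliage: 0.98, soil: 0.02}
    growth_rate_constant: 2.0e-6
    special_loss_rate: 1.0e-4   # lactation (milk lipid export)
    population_biomass: 1.0e8
  - receptor_id: laying_hen
    taxon_class: bird
    habitat: agricultural
    respiration_medium: air
    body_mass: 2.0
    lipid_fraction: 0.1
    ventilation_rate: 0.04
    feeding_rate: 0.07
    water_ingestion: 0.1
    diet: {root_crop: 0.9, soil: 0.1}
    growth_rate_constant: 1.0e-5
    special_loss_rate: 5.0e-5   # egg production
    population_biomass: 1.0e7
  - receptor_id: human
    taxon_class: human
    habitat: terrestrial
    respiration_medium: air
    body_mass: 70.0
    lipid_fraction: 0.15
    ventilation_rate: 0.012
    feeding_rate: 0.021
    water_ingestion: 0.03
    diet:
      piscivorous_fish: 0.05
      dairy_cow: 0.25
      laying_hen: 0.10
      root_crop: 0.35
      foliage: 0.25
    growth_rate_constant: 1.0e-6
    population_biomass: 1.0e9
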