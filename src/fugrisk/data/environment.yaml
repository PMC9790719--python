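# Default evaluative regional environment: 100 000 km^2, 90% land / 10% water
# with underlying sediment, temperate-North-America transport parameters in
# the style of the EQC regional environment.  Every value can be overridden.
total_area: 1.0e11          # m^2
water_area_fraction: 0.10
air_height: 1000.0          # m
water_depth: 20.0           # m
soil_depth: 0.1             # m
sediment_depth: 0.01        # m  (active layer)
temperature: 298.15         # K

# phase volume fractions
vf_aerosol: 2.0e-11         # aerosol in air (~30 ug/m^3)
vf_susp_solids: 5.0e-6      # suspended solids in water
vf_biota: 1.0e-6            # biota in water
vf_soil_air: 0.2
vf_soil_water: 0.3
vf_soil_solids: 0.5
vf_sed_water: 0.8
vf_sed_solids: 0.2

# organic carbon / organic matter fractions
foc_soil: 0.02
foc_sediment: 0.04
foc_susp: 0.2
lipid_biota: 0.05
fom_aerosol: 0.2

# densities, kg/m^3
rho_solids: 2400.0
rho_water: 1000.0
rho_biota: 1000.0
rho_aerosol: 2000.0

# advective residence times, h
tau_air: 100.0
tau_water: 1000.0

# transport parameters (m/h unless noted)
rain_rate: 9.7e-5           # ~0.85 m/yr precipitation
scavenging_ratio: 200000.0  # dimensionless
dry_dep_velocity: 10.8
mtc_air_side: 5.0           # air-side MTC, air-water film and soil boundary layer
mtc_water_side: 0.05        # water-side MTC, air-water film
mtc_soil_air: 0.02          # diffusion in soil air phase
mtc_soil_water: 1.0e-5      # diffusion in soil water phase
mtc_sed_water: 1.0e-4       # water-sediment diffusion
runoff_water: 3.9e-5        # soil water runoff
runoff_solids: 2.3e-8       # soil solids runoff
sed_deposition: 4.6e-8
sed_resuspension: 1.1e-8
sed_burial: 3.4e-8

# vegetation receiving sub-model (steady state with air and soil; no
# feedback on the four-compartment balance)
leaf_area_index: 2.0            # m^2 leaf per m^2 soil
foliage_volume_per_area: 5.0e-4 # m^3 foliage per m^2 soil
lipid_foliage: 0.02             # octanol-equivalent fraction of foliage
mtc_foliage: 9.0                # m/h, foliage-air gaseous exchange
foliage_loss_rate: 1.0e-3       # 1/h, growth dilution + cuticle erosion
particle_interception: 0.2      # fraction of particle flux intercepted
rho_foliage: 900.0              # kg/m^3

# root-crop concentration factor RCF = a + b * KOW^c  (L/kg)
rcf_a: 0.82
rcf_b: 0.03
rcf_c: 0.77
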