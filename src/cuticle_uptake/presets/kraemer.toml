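# Tomato fruit cuticle / CaCl2 droplet preset (isolated astomatous
# cuticle, water-bath receiver).  All values in SI except where the key
# suffix says otherwise.  The five applied masses of Ca used in the
# reference experiment correspond to c_AI0_gL = 1, 5, 10, 15, 30
# (5, 25, 50, 75, 150 ug); the default here is the 10 g/L case used for
# the sensitivity and humidity analyses.

# cuticle
b = 1.87e-5          # thickness, m
rp_max = 2.12e-9     # maximum aqueous-pore radius, m
rho0 = 8.4e14        # aqueous-pore density, 1/m^2 (fitted)
Fs = 1.1             # fractal scaling dimension, - (fitted)
L = 1.0              # control-volume patch length, m
r_H2O = 1.5e-10      # van der Waals radius of water, m
k = 1.07e-15         # surface ion-binding rate constant, m^3/s (fitted)

# solute (CaCl2)
Mw_AI = 110.98       # g/mol
vbar_AI = 1.6e-5     # partial molar volume, m^3/mol
D_AI_bulk = 7.93e-10 # bulk self-diffusion (Ca2+, the slower ion), m^2/s
c_sat = 6.71e3       # saturation concentration at 20 C, mol/m^3

# environment
T = 293.15           # K
H = 0.7              # relative humidity, fraction
Pv = 2338.8          # saturated water vapor pressure, Pa
D_evap = 2.4e-5      # water vapor diffusivity in air, m^2/s
Mw_H2O = 0.018015    # kg/mol
rho_L = 998.2071     # liquid water density, kg/m^3
vbar_H2O = 1.8047e-5 # partial molar volume of water, m^3/mol
D_H2O_bulk = 2.299e-9 # bulk water self-diffusion, m^2/s
delta = 1.994        # evaporation rate constant, -

# droplet
V0 = 1e-9            # initial drop volume, m^3
theta0_deg = 99.2    # initial contact angle, degrees
c_AI0_gL = 10.0      # initial AI concentration, g/L
n_drops = 5
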