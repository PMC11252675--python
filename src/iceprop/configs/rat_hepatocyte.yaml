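# Rat hepatocyte biophysical parameters (flat key-value).
# V_iso: 21 um diameter sphere; n_s: isotonic 0.155 M NaCl in the active water.
A: 1.412e3        # membrane surface area [um^2]
Lpg: 1.5e-12      # hydraulic conductivity at T_R [m^3/N/s]
ELp: 3.42e5       # activation energy [J/mol]
T_R: 273.15       # reference temperature [K]
Tf0: 272.63       # isotonic cytoplasm freezing point [K]
v_w: 1.8e13       # molar volume of water [um^3/mol]
v_s: 2.0          # NaCl dissociation number
dHf_pv: 5.94124e16  # latent heat of fusion [um^3 atm/mol]
v_b: 0.51         # osmotically inactive volume fraction
V_iso: 4849.0482608158451  # isotonic cell volume [um^3]
n_s: 3.6828521540896354e-13  # intracellular salt [mol]
Omega0: 1.1e10    # kinetic nucleation coefficient [1/m^2/s]
kappa0: 1.4e9     # thermodynamic nucleation coefficient [K^5]
phi_hydro: 0.609  # hydrodynamic interaction constant
Rgas: 8.314       # gas constant [J/mol/K]
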