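# Reference chamber configuration (reconstruction; see README notes).
# One open side to the flow channel; interior pre-loaded with polymer.
lattice:
  n_rows: 50
  n_cols: 50
  spacing: 1.0
  boundary_values: {P: 0.1, E: 0.0, O: 0.0}
transport:
  D_P: 30.0       # polymer diffusivity, um^2/h
  D_E: 2000.0     # enzyme
  D_O: 4000.0     # oligomer
  d_rel: 1.0      # relative (free-water-normalized) multiplier
depoly:
  k_cat: 7.0      # 1/h per mg/L enzyme
  K_P: 0.05       # mg/L
  conv: 1.0
kinetics:
  K_enz: 0.1      # enzymatic activity, 1/h
  mu_max: 0.5     # 1/h
  K_m: 0.002      # mg/L
  Y: 0.5
  site_mass: 20.0
rho: 0.3          # cells per um^2
duration: 20.0    # h
dt: 0.005         # h
seed: 0
boundary_mode: open-side
grids:            # used by `polychamber sweep`
  rho: [0.05, 0.1, 0.2, 0.3, 0.45, 0.6]
  K_enz: [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7]
  d_rel: [0.001, 0.01, 0.1, 1.0]
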