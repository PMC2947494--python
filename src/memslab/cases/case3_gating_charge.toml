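"Calculation type" = "Gating charge"
"PQR file 1" = "3EMN_open.pqr"
"PQR file 2" = "closed_state.pqr"
"Grid dimensions" = 161
"Coarse grid lengths" = 300.0
"Medium grid lengths" = 120.0
"Fine grid lengths" = 60.0
"Counter-ions" = [[1.0, 0.10, 2.0], [-1.0, 0.10, 2.0]]
"Protein dielectric" = 5.0
"Solvent dielectric" = 80.0
"Membrane dielectric" = 2.0
"Headgroup dielectric" = 80.0
"Solution method" = "lpbe"
"Boundary condition" = "Membrane potential"
"Solvent probe radius (srad)" = 1.4
"Surface sphere density (sdens)" = 10.0
"Temperature" = 298.15
"Z-position of membrane bottom" = -14.0
"Membrane thickness" = 28.0
"Head group thickness" = 0.0
"Upper exclusion radius" = 18.5
"Lower exclusion radius" = 18.5
"Membrane potential (mV)" = 50.0
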