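"Calculation type" = "Protein solvation"
"PQR file 1" = "Helix.pqr"
"Grid dimensions" = 161
"Coarse grid lengths" = 200.0
"Medium grid lengths" = 100.0
"Fine grid lengths" = 50.0
"Counter-ions" = [[1.0, 0.10, 2.0], [-1.0, 0.10, 2.0]]
"Protein dielectric" = 5.0
"Solvent dielectric" = 80.0
"Membrane dielectric" = 2.0
"Headgroup dielectric" = 80.0
"Solution method" = "lpbe"
"Boundary condition" = "Focus"
"Solvent probe radius (srad)" = 1.4
"Surface sphere density (sdens)" = 10.0
"Temperature" = 298.15
"Z-position of membrane bottom" = -21.0
"Membrane thickness" = 42.0
"Head group thickness" = 8.0
"Upper exclusion radius" = 0.0
"Lower exclusion radius" = 0.0
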