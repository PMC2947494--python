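"Calculation type" = "Ion solvation"
"PQR file 1" = "KcsA.pqr"
"PQR file 2" = "K_ion.pqr"
"Grid dimensions" = 161
"Coarse grid lengths" = 300.0
"Medium grid lengths" = 120.0
"Fine grid lengths" = 60.0
"Counter-ions" = [[1.0, 0.03, 2.0], [-1.0, 0.03, 2.0]]
"Protein dielectric" = 2.0
"Solvent dielectric" = 80.0
"Membrane dielectric" = 2.0
"Headgroup dielectric" = 80.0
"Solution method" = "lpbe"
"Boundary condition" = "Focus"
"Solvent probe radius (srad)" = 1.4
"Surface sphere density (sdens)" = 10.0
"Temperature" = 298.15
"Z-position of membrane bottom" = -12.0
"Membrane thickness" = 24.0
"Head group thickness" = 0.0
"Upper exclusion radius" = 24.0
"Lower exclusion radius" = 16.0
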