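# Default transformation-unit table: 22 net photochemical formula changes for
# dissolved organic matter. The nine units that dominate published photolysis
# discussions (-CO2, -H2O, -SO3, -CO, +O, +O2, -H2+O, +NO2-H, +O-NH) are taken
# verbatim; the remaining entries are reconstructed from the standard DOM
# photochemistry reaction compilations (small-fragment eliminations,
# oxidations and hydrogenations). Replace via --units to use your own set.
name,dC,dH,dN,dO,dS
-CO2,-1,0,0,-2,0
-CO,-1,0,0,-1,0
-H2O,0,-2,0,-1,0
-SO3,0,0,0,-3,-1
+O,0,0,0,1,0
+O2,0,0,0,2,0
-H2+O,0,-2,0,1,0
+NO2-H,0,-1,1,2,0
+O-NH,0,-1,-1,1,0
+H2,0,2,0,0,0
-H2,0,-2,0,0,0
+H2O,0,2,0,1,0
-O,0,0,0,-1,0
-CH2,-1,-2,0,0,0
-CH2O,-1,-2,0,-1,0
-CH2O2,-1,-2,0,-2,0
-CH4O,-1,-4,0,-1,0
-C2H2O,-2,-2,0,-1,0
-C2H4,-2,-4,0,0,0
-C2H4O2,-2,-4,0,-2,0
-NH3,0,-3,-1,0,0
-H2S,0,-2,0,0,-1
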