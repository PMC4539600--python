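# Synthetic qualitative reference trends (NOT experimental data).
# Idealized longitudinal response shapes used only as trend_compare
# references: unitless, normalized to a maximum of 1.
profile,position_um,value
auxin_response,0,0.62
auxin_response,25,0.85
auxin_response,50,1.00
auxin_response,100,0.74
auxin_response,200,0.52
auxin_response,350,0.40
auxin_response,550,0.33
auxin_response,800,0.29
auxin_response,1000,0.27
pls_response,0,0.92
pls_response,50,1.00
pls_response,120,0.84
pls_response,250,0.62
pls_response,450,0.45
pls_response,700,0.34
pls_response,1000,0.28
ethylene_response,0,0.30
ethylene_response,200,0.38
ethylene_response,450,0.55
ethylene_response,700,0.78
ethylene_response,1000,1.00
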