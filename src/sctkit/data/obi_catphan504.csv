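material,hu,relative_ed,mass_density
Acrylic [C5H8O2],40,1.147,1.180
"Air [.78N,.21O,.01Ar]",-934,0.001,0.001
Polystyrene [C8H8],-81,0.998,1.050
LDPE [C2H4],-100,0.945,0.904
PMP [C6H12(CH2)],-202,0.853,0.830
Teflon [CF2],888,1.868,2.200
Max,6000,3.920,9.500
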