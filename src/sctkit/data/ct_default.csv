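material,hu,relative_ed,mass_density
Air,-1000,0.001,0.001
Lung (inhale),-700,0.290,0.290
Lung (exhale),-500,0.500,0.500
Adipose,-96,0.952,0.945
Water,0,1.000,1.000
Muscle,47,1.042,1.050
Trabecular bone,237,1.117,1.160
Dense bone,923,1.512,1.610
Cortical max,3000,2.751,2.900
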