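# Per-element constants used for carbon-scaled atomic weighting.
# mass: IUPAC 2021 standard atomic weights (abridged).
# sanderson_en: Sanderson electronegativities (Sanderson, J. Chem. Educ. 1988, 65, 112).
# vdw_volume: (4/3)*pi*r^3 in cubic angstroms from Bondi van der Waals radii
#   (Bondi, J. Phys. Chem. 1964, 68, 441); B from Batsanov, Inorg. Mater. 2001, 37, 871.
element,mass,sanderson_en,vdw_volume
H,1.008,2.592,7.2382
B,10.81,2.275,29.6506
C,12.011,2.746,20.5795
N,14.007,3.194,15.5986
O,15.999,3.654,14.7107
F,18.998403,4.000,13.3057
Si,28.085,2.138,38.7925
P,30.973762,2.515,24.4290
S,32.06,2.957,24.4290
Cl,35.45,3.475,22.4493
Br,79.904,3.219,26.5218
I,126.90447,2.778,32.5154
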