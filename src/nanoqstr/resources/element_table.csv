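# Embedded element constants, version 1. Sources: atomic numbers IUPAC;
# Pauling electronegativities and first ionization energies (eV), CRC
# Handbook of Chemistry and Physics; van der Waals radii (pm), consistent
# set of Alvarez, Dalton Trans. 42 (2013) 8617 (main group values agree
# with Mantina et al. 2009); metal/semimetal/nonmetal classification per
# the common periodic-table convention.
symbol,atomic_number,electronegativity_pauling,ionization_energy_ev,vdw_radius_pm,classification
H,1,2.20,13.598,120,nonmetal
C,6,2.55,11.260,177,nonmetal
N,7,3.04,14.534,166,nonmetal
O,8,3.44,13.618,150,nonmetal
Na,11,0.93,5.139,250,metal
Mg,12,1.31,7.646,251,metal
Al,13,1.61,5.986,225,metal
Si,14,1.90,8.152,219,semimetal
S,16,2.58,10.360,189,nonmetal
Cl,17,3.16,12.968,182,nonmetal
Ti,22,1.54,6.828,246,metal
Mn,25,1.55,7.434,245,metal
Fe,26,1.83,7.902,244,metal
Ni,28,1.91,7.640,240,metal
Cu,29,1.90,7.726,238,metal
Zn,30,1.65,9.394,239,metal
Ag,47,1.93,7.576,253,metal
Cd,48,1.69,8.994,243,metal
Ce,58,1.12,5.539,242,metal
Au,79,2.54,9.226,232,metal
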