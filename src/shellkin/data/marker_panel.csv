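locus,multiplex,k,n_genotyped,h_obs,h_exp,hwe_p,primer_conc_pmol_ul
Pmv17,1,19,233,0.906,0.912,0.50,0.5
UNH890,1,6,232,0.414,0.436,0.73,1.0
UNH908,1,25,235,0.843,0.875,0.36,3.0
Gm634,1,15,234,0.799,0.818,0.42,1.0
Ppun9,1,21,233,0.674,0.748,0.02,0.5
Hchi59,1,17,232,0.845,0.864,0.52,1.0
UNH216,1,11,232,0.603,0.584,0.83,4.0
UME002,1,7,228,0.610,0.627,0.44,4.0
Pmv3,2,31,237,0.768,0.775,0.04,1.0
GM264,2,17,234,0.850,0.859,0.42,4.0
Ppun5,2,23,233,0.695,0.722,0.19,3.0
TmoM13,2,25,234,0.829,0.907,0.44,4.0
TmoM25,2,4,231,0.732,0.671,0.55,2.0
Hchi36,2,4,230,0.539,0.559,0.44,1.0
UME003,2,17,232,0.897,0.869,0.56,2.0
TmoM11,3,7,234,0.667,0.677,0.87,1.5
UNH2075,3,19,233,0.773,0.770,0.23,2.5
NP101,3,18,232,0.810,0.749,0.02,3.5
Pzeb4,3,8,232,0.612,0.610,0.98,2.0
UNH974,3,33,219,0.863,0.926,0.60,4.0
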