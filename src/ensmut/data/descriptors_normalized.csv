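# Normalized per-mutation descriptor values for the reported deleterious
# missense mutations in human lysosomal alpha-mannosidase, computed from MD
# conformational ensembles. All four descriptors are normalized to [0, 1] by
# the maximum of their series. ddg_capped / ddg_sd_capped = 1 where the raw
# stability change exceeded the 20.35 kcal/mol normalizing cap; active_site = 1
# where the residue is part of the 10-residue active-site set (its MI and
# bond-to-bond couplings to the site are reported as 0 by convention).
mutation,chain,group,total_dihedral_mi,ddg_norm,ddg_sd_norm,b2b_propensity,ddg_capped,ddg_sd_capped,active_site
C55F,A,folding,0.122,0.172,0.056,0.419,0,0,0
A95P,A,folding,0.162,0.257,0.058,0.720,0,0,0
P197R,A,folding,0.626,1.000,0.178,0.499,1,0,0
R202P,A,folding,0.323,0.011,0.059,0.770,0,0,0
L352P,A,folding,0.127,0.209,0.066,0.583,0,0,0
T355P,B,folding,0.126,0.141,0.071,0.548,0,0,0
P356R,B,folding,0.131,0.343,0.152,0.607,0,0,0
G390C,B,folding,0.181,0.603,0.145,0.219,0,0,0
H445Y,C,folding,0.732,0.929,1.000,0.574,0,0,0
S453Y,C,folding,1.000,0.495,0.205,0.389,0,0,0
S453F,C,folding,1.000,0.495,0.205,0.389,0,0,0
L565P,C,folding,0.359,0.294,0.087,0.929,0,0,0
W714R,D,folding,0.145,0.270,0.087,0.751,0,0,0
R750W,D,folding,0.514,0.106,0.085,0.912,0,0,0
G800W,D,folding,0.125,1.000,0.192,0.552,1,0,0
G800R,D,folding,0.125,1.000,0.515,0.552,1,0,0
L809P,D,folding,0.175,0.285,0.186,0.798,0,0,0
G891R,E,folding,0.147,0.714,0.066,0.709,0,0,0
L892P,E,folding,0.207,0.220,0.232,0.856,0,0,0
R916C,E,folding,0.263,0.182,0.052,0.799,0,0,0
R916H,E,folding,0.263,0.764,0.620,0.799,0,0,0
L956R,E,folding,0.202,0.182,0.085,0.794,0,0,0
F1000S,E,folding,0.121,0.295,0.040,0.751,0,0,0
H72L,A,activity,0.000,0.077,0.094,0.000,0,0,1
D74E,A,activity,0.000,0.048,0.065,0.000,0,0,1
Y99H,A,activity,0.349,0.116,0.039,0.521,0,0,0
D102N,A,activity,0.161,0.091,0.038,0.492,0,0,0
G153V,A,activity,0.588,0.623,0.157,0.020,0,0,0
D159N,A,activity,0.768,0.122,0.043,0.807,0,0,0
H200L,A,activity,0.358,1.000,1.000,0.607,1,1,0
H200N,A,activity,0.358,1.000,1.000,0.607,1,1,0
R229W,A,activity,0.660,0.092,0.072,0.650,0,0,0
P263L,A,activity,0.147,0.132,0.120,0.314,0,0,0
S318L,A,activity,0.476,0.085,0.057,0.127,0,0,0
P379L,B,activity,0.188,0.208,0.096,0.569,0,0,0
G420V,B,activity,0.112,0.301,0.069,0.371,0,0,0
G451C,C,activity,0.420,0.514,0.175,0.591,0,0,0
V457E,C,activity,0.681,0.266,0.091,0.448,0,0,0
T745R,D,activity,0.527,0.559,0.179,0.723,0,0,0
R950P,E,activity,0.133,0.213,0.043,0.609,0,0,0
L518P,C,unclassified,0.180,0.272,0.096,0.587,0,0,0
G801D,D,unclassified,0.230,0.485,0.168,0.338,0,0,0
R916S,E,unclassified,0.120,0.227,0.058,0.799,0,0,0
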