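# Reported deleterious missense mutations in human lysosomal alpha-mannosidase
# (hLAMAN, precursor numbering incl. signal peptide). Groups: folding = impaired
# folding/trafficking, activity = reduced enzymatic activity with intact folding,
# unclassified = effect not yet assigned. distance_to_zn is the distance of the
# mutated residue to the catalytic Zn(2+) in Angstrom; contact_chains lists other
# chains within contact ('-' = none). relative_activity is % of wild type
# ('N.D.' = no data).
mutation,chain,group,relative_activity,distance_to_zn,secondary_structure,contact_chains
C55F,A,folding,9,27.3,SS-bond,B
A95P,A,folding,10,13.0,Loop,-
P197R,A,folding,12,7.0,Loop,C
R202P,A,folding,24,20.0,alpha-helix 8,C;D
L352P,A,folding,11,26.0,beta-sheet 9,-
T355P,B,folding,9,19.4,alpha-helix 13,-
P356R,B,folding,6,17.9,alpha-helix 13,-
G390C,B,folding,7,17.1,beta-turn,D
H445Y,C,folding,6,8.2,Loop,A
S453Y,C,folding,19,10.2,Loop,A
S453F,C,folding,19,10.2,Loop,A
L565P,C,folding,22,45.1,beta-sheet 20,D
W714R,D,folding,5,32.1,beta-sheet 31,-
R750W,D,folding,8,24.7,beta-sheet 34,A;E
G800W,D,folding,5,20.8,beta-sheet 38,B
G800R,D,folding,8,20.8,beta-sheet 38,B
L809P,D,folding,4,31.7,beta-sheet 39,-
G891R,E,folding,5,40.7,Loop,B;C
L892P,E,folding,11,41.8,Loop,B
R916C,E,folding,16,29.8,beta-sheet 39,A
R916H,E,folding,13,29.8,beta-sheet 39,A
L956R,E,folding,8,24.8,beta-turn,A
F1000S,E,folding,11,32.4,beta-sheet 47,-
H72L,A,activity,17,6.5,Active site,-
D74E,A,activity,11,5.0,Active site,-
Y99H,A,activity,9,18.5,alpha-helix 3,-
D102N,A,activity,15,21.0,alpha-helix 3,-
G153V,A,activity,19,14.9,Loop,-
D159N,A,activity,10,9.7,Loop,B;C
H200L,A,activity,25,13.9,Loop,-
H200N,A,activity,53,13.9,Loop,-
R229W,A,activity,30,23.7,alpha-helix 9,C;D
P263L,A,activity,9,15.4,Loop,-
S318L,A,activity,32,9.3,Loop,-
P379L,B,activity,19,18.1,Loop,D
G420V,B,activity,15,37.6,Loop,E
G451C,C,activity,30,12.9,Loop,B;D
V457E,C,activity,33,14.0,alpha-helix 17,A
T745R,D,activity,18,25.5,beta-sheet 33,-
R950P,E,activity,16,41.2,beta-sheet 47,-
L518P,C,unclassified,N.D.,34.5,beta-sheet 15,D
G801D,D,unclassified,N.D.,24.3,beta-sheet 38,B
R916S,E,unclassified,N.D.,29.8,beta-sheet 45,A
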