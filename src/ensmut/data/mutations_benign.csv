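# Benign/neutral missense variants of human lysosomal alpha-mannosidase
# detected in patients; these enzyme variants retain 37-124% of wild-type
# activity (range noted as free text, not parsed per variant). Chains assigned
# from the precursor cleavage points (A: <=345, B: 346-429, C: 430-601,
# D: 602-882, E: >=883). Structural annotations were not reported.
mutation,chain,group,relative_activity,distance_to_zn,secondary_structure,contact_chains
P248L,A,benign,37-124,,,-
L278V,A,benign,37-124,,,-
P282S,A,benign,37-124,,,-
T312I,A,benign,37-124,,,-
R337Q,A,benign,37-124,,,-
E402K,B,benign,37-124,,,-
N413S,B,benign,37-124,,,-
A481S,C,benign,37-124,,,-
P669L,D,benign,37-124,,,-
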