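>AP1_synthetic	AP-1 (FOS::JUN) consensus-derived synthetic matrix TGA(C/G)TCA
A  [  3  3 91  1  3  3 91 ]
C  [  3  3  3 50  3 91  3 ]
G  [  3 91  3 48  3  3  3 ]
T  [ 91  3  3  1 91  3  3 ]
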