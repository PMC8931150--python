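specimen_id,true_sex,method,biological_replicate,cnv
F1,F,ddPCR,1,2.011
F1,F,ddPCR,2,2.009
F1,F,qPCR,1,2.024
F1,F,qPCR,2,1.985
F2,F,ddPCR,1,1.993
F2,F,ddPCR,2,1.987
F2,F,qPCR,1,1.899
F2,F,qPCR,2,1.966
F3,F,ddPCR,1,2.007
F3,F,ddPCR,2,2.011
F3,F,qPCR,1,2.057
F3,F,qPCR,2,2.096
F4,F,ddPCR,1,1.975
F4,F,ddPCR,2,1.978
F4,F,qPCR,1,2.041
F4,F,qPCR,2,1.987
F5,F,ddPCR,1,2.018
F5,F,ddPCR,2,2.009
F5,F,qPCR,1,1.874
F5,F,qPCR,2,1.993
F6,F,ddPCR,1,1.971
F6,F,ddPCR,2,1.965
F6,F,qPCR,1,1.941
F6,F,qPCR,2,2.051
F7,F,ddPCR,1,1.983
F7,F,ddPCR,2,1.991
F7,F,qPCR,1,2.065
F7,F,qPCR,2,1.997
F8,F,ddPCR,1,2.019
F8,F,ddPCR,2,2.016
F8,F,qPCR,1,1.873
F8,F,qPCR,2,2.014
F9,F,ddPCR,1,1.971
F9,F,ddPCR,2,1.968
F9,F,qPCR,1,1.885
F9,F,qPCR,2,1.915
F10,F,ddPCR,1,1.993
F10,F,ddPCR,2,1.971
F10,F,qPCR,1,1.912
F10,F,qPCR,2,1.888
M1,M,ddPCR,1,0.968
M1,M,ddPCR,2,0.979
M1,M,qPCR,1,1.012
M1,M,qPCR,2,1.026
M2,M,ddPCR,1,1.021
M2,M,ddPCR,2,1.011
M2,M,qPCR,1,0.931
M2,M,qPCR,2,0.975
M3,M,ddPCR,1,0.981
M3,M,ddPCR,2,0.987
M3,M,qPCR,1,1.017
M3,M,qPCR,2,1.002
M4,M,ddPCR,1,1.011
M4,M,ddPCR,2,1.024
M4,M,qPCR,1,1.025
M4,M,qPCR,2,0.999
M5,M,ddPCR,1,1.001
M5,M,ddPCR,2,0.998
M5,M,qPCR,1,0.899
M5,M,qPCR,2,0.891
M6,M,ddPCR,1,1.014
M6,M,ddPCR,2,1.012
M6,M,qPCR,1,0.916
M6,M,qPCR,2,1.012
M7,M,ddPCR,1,0.999
M7,M,ddPCR,2,0.991
M7,M,qPCR,1,1.036
M7,M,qPCR,2,1.036
M8,M,ddPCR,1,1.021
M8,M,ddPCR,2,1.009
M8,M,qPCR,1,0.877
M8,M,qPCR,2,1.023
M9,M,ddPCR,1,0.987
M9,M,ddPCR,2,0.995
M9,M,qPCR,1,0.955
M9,M,qPCR,2,0.881
M10,M,ddPCR,1,1.021
M10,M,ddPCR,2,1.036
M10,M,qPCR,1,0.931
M10,M,qPCR,2,0.989
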