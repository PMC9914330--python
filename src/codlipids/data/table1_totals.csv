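measure,unit,norway,iceland,alaska,sem,p_species,p_origin
TL,g/100 g,1.1,1.8,1.3,0.559,0.889,0.498
TCHR,mg/100 g,70.44,68.45,70.02,2.996,0.875,0.843
alpha_tocopherol,ug/g,4.90,4.97,8.04,0.677,0.001,0.996
SFA,mg/g,1.573,2.076,1.806,0.176,0.934,0.050
MUFA,mg/g,0.885,1.212,1.023,0.080,0.796,0.006
PUFA,mg/g,3.263,3.266,3.405,0.308,0.712,0.996
n6,mg/g,0.201,0.215,0.218,0.021,0.686,0.654
n3,mg/g,3.025,3.010,3.151,0.286,0.705,0.971
P_S,,0.047,0.043,0.051,0.003,0.113,0.353
n3_n6,,15.09,14.67,14.84,1.029,0.819,0.863
h_H,,2.812,2.196,2.666,0.065,0.049,<0.001
AI,,0.387,0.465,0.383,0.011,0.002,<0.001
TI,,0.015,0.019,0.017,0.001,0.989,0.003
PI,,3.791,3.313,3.745,0.049,0.003,<0.001
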