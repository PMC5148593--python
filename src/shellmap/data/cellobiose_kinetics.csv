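mutation,Km_mM,kcat_s,efficiency_printed,relative_printed,method
WT,2.36,2.61,1.11,,michaelis_menten
D84A,,,0.0125,0.011,pseudo_first_order
R97A,,,0.0014,0.0013,pseudo_first_order
S247A,3.32,2.89,0.87,0.79,michaelis_menten
N249A,1.3,7.52,5.78,5.23,michaelis_menten
F251A,1.04,0.74,0.71,0.64,michaelis_menten
F334A,0.33,1.08,3.22,2.91,michaelis_menten
L350A,4.51,3.31,0.73,0.66,michaelis_menten
S358A,0.93,0.09,0.094,0.085,michaelis_menten
K366A,1.63,1.65,0.98,0.89,michaelis_menten
Y420A,3.1,0.99,0.32,0.29,michaelis_menten
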