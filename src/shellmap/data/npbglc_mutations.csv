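mutation,position,wt_aa,mut_aa,substrate,relative_efficiency,source
T35A,35,T,A,NPbglc,0.208,mendonca_marana_2011
Q39A,39,Q,A,NPbglc,0.00012,marana_2002
Q39E,39,Q,E,NPbglc,0.013,marana_2004
Q39N,39,Q,N,NPbglc,0.00063,marana_2004
W54A,54,W,A,NPbglc,0.022,tamaki_2014
M57A,57,M,A,NPbglc,0.765,tamaki_2014
P62A,62,P,A,NPbglc,0.094,tamaki_2014
D84A,84,D,A,NPbglc,inactive,new_panel
R97A,97,R,A,NPbglc,0.0000008,new_panel
R97M,97,R,M,NPbglc,0.021,mendonca_marana_2011
F98A,98,F,A,NPbglc,inactive,tamaki_2014
W143A,143,W,A,NPbglc,0.00036,tamaki_2014
E187D,187,E,D,MUbglc,0.00044,marana_2003
P188A,188,P,A,NPbglc,0.00021,tamaki_2014
R189G,189,R,G,NPbglc,3.3,mendonca_marana_2011
R189A,189,R,A,NPbglc,0.004,mendonca_marana_2011
E190A,190,E,A,NPbglc,0.213,mendonca_marana_2008
E190Q,190,E,Q,NPbglc,0.120,mendonca_marana_2008
E194A,194,E,A,NPbglc,0.184,mendonca_marana_2008
G195L,195,G,L,NPbglc,0.112,tamaki_2014
Y196A,196,Y,A,NPbglc,0.066,tamaki_2014
K201A,201,K,A,NPbglc,0.10,mendonca_marana_2008
K201F,201,K,F,NPbglc,1.3,mendonca_marana_2008
P203A,203,P,A,NPbglc,0.059,tamaki_2014
H223A,223,H,A,NPbglc,0.026,tamaki_2014
S247A,247,S,A,NPbglc,3.5,new_panel
N249A,249,N,A,NPbglc,3.5,new_panel
F251A,251,F,A,NPbglc,0.538,new_panel
Y331F,331,Y,F,NPbglc,0.016,mendonca_marana_2011
F334A,334,F,A,NPbglc,2.6,new_panel
L350A,350,L,A,NPbglc,3.2,new_panel
S358F,358,S,F,NPbglc,0.358,mendonca_marana_2011
S358A,358,S,A,NPbglc,0.569,mendonca_marana_2011
K366A,366,K,A,NPbglc,2.0,new_panel
S378G,378,S,G,NPbglc,0.134,mendonca_marana_2011
T398A,398,T,A,NPbglc,inactive,tamaki_2014
N400D,400,N,D,NPbglc,0.00265,mendonca_marana_2011
N400A,400,N,A,NPbglc,0.0027,mendonca_marana_2011
N400V,400,N,V,NPbglc,0.014,mendonca_marana_2011
Y420A,420,Y,A,NPbglc,1.6,new_panel
S424F,424,S,F,NPbglc,0.0038,mendonca_marana_2011
E451A,451,E,A,NPbglc,0.000011,marana_2002
E451Q,451,E,Q,NPbglc,0.0404,marana_2004
E451D,451,E,D,NPbglc,0.0033,marana_2004
E451S,451,E,S,NPbglc,0.000101,marana_2004
W452A,452,W,A,NPbglc,inactive,tamaki_2014
M453A,453,M,A,NPbglc,0.48,mendonca_marana_2008
F460A,460,F,A,NPbglc,0.0013,tamaki_2014
F460L,460,F,L,NPbglc,0.006,mendonca_marana_2011
R474H,474,R,H,NPbglc,0.0054,mendonca_marana_2011
R474A,474,R,A,NPbglc,0.013,mendonca_marana_2011
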