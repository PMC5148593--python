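position,wt_aa,layer,association,constrained_association
35,T,1,GBS+CR,
39,Q,0,GBS,
54,W,1,GBS+ABS,
57,M,1,ABS,
62,P,2,GBS+ABS,
84,D,2,GBS+CR,
97,R,0,CR,
98,F,1,CR,
143,W,1,GBS+ABS+CR,
187,E,0,CR,
188,P,1,GBS+ABS+CR,
189,R,1,ABS+CR,
190,E,0,ABS,
194,E,0,ABS,
195,G,1,ABS,
196,Y,1,ABS,
201,K,0,ABS,
203,P,1,ABS,
223,H,2,GBS+CR,
247,S,1,ABS+CR,
249,N,1,ABS+CR,
251,F,2,ABS+CR,
331,Y,0,CR,
334,F,1,ABS,
350,L,2,ABS,
358,S,2,ABS,
366,K,2,GBS+ABS+CR,ABS
378,S,1,CR,
398,T,1,CR,
400,N,1,GBS+CR,
420,Y,1,CR,
424,S,2,GBS+CR,
451,E,0,GBS,
452,W,0,GBS,
453,M,0,ABS,
460,F,1,GBS+ABS,
474,R,2,GBS,
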