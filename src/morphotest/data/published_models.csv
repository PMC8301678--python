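set,target,intercept,slope
WSBL,Ptros_from_PT,-2.4,5.4
BH,Ptros_from_PT,-3.9,5.0
GOM,Ptros_from_PT,-2.3,6.2
BALT,Ptros_from_PT,-0.6,11.6
NORW,Ptros_from_PT,-0.5,3.7
WSBL,NPV_from_Ptros,3.7,-4.9
BH,NPV_from_Ptros,3.3,-4.8
GOM,NPV_from_Ptros,4.7,-8.1
BALT,NPV_from_Ptros,2.7,-5.4
NORW,NPV_from_Ptros,3.1,-5.0
WSBL,PPV_from_Ptros,0.2,3.2
BH,PPV_from_Ptros,-2.1,4.7
GOM,PPV_from_Ptros,-0.6,4.9
BALT,PPV_from_Ptros,-0.4,3.9
NORW,PPV_from_Ptros,-1.5,6.3
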