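staff,PCG,FIN,SCF,TECH,score,level
1,0.184,0.5,0.0947,0.731,0.107,very low
2,0.244,0.387,0.428,0.633,0.494,moderate
3,0.628,0.402,0.564,0.716,0.529,moderate
4,0.718,0.538,0.663,0.716,0.507,moderate
5,0.898,0.643,0.761,0.867,0.896,high
6,0.534,0.312,0.303,0.264,0.767,high
7,0.695,0.620,0.375,0.913,0.625,moderate
8,0.237,0.199,0.337,0.223,0.378,low
9,0.959,0.635,0.936,0.875,0.916,extremely high
10,0.750,0.519,0.511,0.772,0.620,moderate
11,0.146,0.332,0.153,0.690,0.130,very low
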