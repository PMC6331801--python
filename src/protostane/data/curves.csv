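analyte,rt_min,slope,intercept,linear_low,linear_high,r,lod_ng_ml,loq_ng_ml
16-oxo-alisol A 23-acetate,1.48,15.87,-0.014,0.008,0.103,0.9999,1.17,3.91
16-oxo-alisol A 24-acetate,1.71,17.21,-0.002,0.009,0.138,0.9990,1.82,6.05
alisol C,1.95,5.005,-0.043,0.037,1.490,0.9980,3.63,12.1
alisol F,2.78,2.496,-0.013,0.062,1.125,0.9989,2.45,8.17
alisol C 23-acetate,2.87,9.118,-0.029,0.045,1.352,0.9990,1.70,5.67
alisol L,3.10,12.22,-0.054,0.024,0.652,0.9996,1.68,5.59
alisol F 24-acetate,3.25,2.160,-0.038,0.078,1.060,0.9990,7.01,21.0
alisol A,3.38,3.125,-0.016,0.066,3.333,0.9982,1.61,5.35
alisol A 23-acetate,3.54,3.441,-0.017,0.042,1.080,0.9993,1.73,5.75
alisol A 24-acetate,4.05,3.505,-0.010,0.049,3.240,0.9990,1.01,4.37
alisol G,4.61,6.788,-0.019,0.026,0.525,0.9980,3.63,12.1
alisol B,4.84,1.635,-0.013,0.197,5.444,0.9982,3.40,10.6
alisol B 23-acetate,5.67,2.678,-0.023,0.294,9.790,0.9993,3.04,10.1
11-deoxy-alisol B,6.36,2.584,-0.058,0.089,1.740,0.9990,9.23,27.4
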