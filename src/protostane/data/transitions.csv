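peak,analyte,precursor_mz,product_mz,cone_voltage,collision_energy,is_internal_standard
1,16-oxo-alisol A 23-acetate,529.34,451.34,30,18,False
2,16-oxo-alisol A 24-acetate,529.34,451.34,30,18,False
3,alisol C,487.33,415.35,40,18,False
4,alisol F,471.33,339.33,35,12,False
5,alisol C 23-acetate,529.32,451.32,40,21,False
6,alisol L,469.31,397.31,35,22,False
7,alisol F 24-acetate,513.31,339.33,35,12,False
8,alisol A,473.39,383.39,40,11,False
9,alisol A 23-acetate,497.36,365.36,40,16,False
10,alisol A 24-acetate,497.36,365.36,40,15,False
IS,glycyrrhetinic acid,471.32,317.28,40,28,True
11,alisol G,455.31,437.31,35,10,False
12,alisol B,455.31,437.31,40,11,False
13,alisol B 23-acetate,497.29,437.29,40,11,False
14,11-deoxy-alisol B,479.31,479.31,45,10,False
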