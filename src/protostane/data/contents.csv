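sample_id,origin,16-oxo-alisol A 23-acetate,16-oxo-alisol A 24-acetate,alisol C,alisol F,alisol C 23-acetate,alisol L,alisol F 24-acetate,alisol A,alisol A 23-acetate,alisol A 24-acetate,alisol G,alisol B,alisol B 23-acetate,11-deoxy-alisol B
S1,Fujian,0.009,0.008,0.055,0.041,0.121,0.012,0.082,0.067,0.029,0.052,0.020,0.307,1.420,0.180
S2,Fujian,0.006,0.007,0.068,0.044,0.113,0.013,0.081,0.069,0.032,0.061,0.020,0.325,1.546,0.177
S3,Fujian,0.006,0.007,0.027,0.063,0.118,0.013,ND,0.075,0.030,0.069,0.024,0.118,1.560,0.183
S4,Fujian,0.006,0.008,0.025,0.047,0.219,0.018,0.08,0.070,0.021,0.028,0.020,0.324,1.216,0.124
S5,Fujian,0.005,0.005,0.023,0.046,0.204,0.018,0.081,0.081,0.023,0.028,0.021,0.291,1.780,0.122
S6,Fujian,0.006,0.007,0.027,0.049,0.244,0.020,0.085,0.075,0.024,0.030,0.025,0.342,1.502,0.131
S7,Fujian,0.007,0.008,0.070,0.057,0.141,0.014,ND,0.079,0.031,0.061,0.023,0.246,1.459,0.127
S8,Fujian,0.006,0.009,0.045,0.048,0.153,0.013,0.081,0.080,0.032,0.062,0.021,0.237,1.451,0.095
S9,Fujian,0.006,0.006,0.022,0.042,0.113,0.014,0.082,0.069,0.047,0.053,0.027,0.104,1.273,0.133
S10,Fujian,0.005,0.007,0.024,0.048,0.099,0.018,0.083,0.082,0.024,0.029,0.022,0.333,1.769,0.121
S11,Fujian,0.008,0.008,0.054,0.042,0.121,0.013,0.082,0.068,0.029,0.051,0.020,0.308,1.420,0.181
S12,Fujian,0.007,0.007,0.067,0.044,0.114,0.013,0.081,0.069,0.032,0.061,0.020,0.326,1.546,0.178
S13,Fujian,0.006,0.007,0.027,0.063,0.118,0.013,ND,0.075,0.030,0.069,0.024,0.118,1.560,0.183
S14,Fujian,0.005,0.008,0.026,0.048,0.219,0.019,0.08,0.070,0.021,0.029,0.021,0.324,1.216,0.124
S15,Fujian,0.006,0.005,0.024,0.046,0.205,0.018,0.082,0.081,0.024,0.028,0.021,0.291,1.780,0.122
S16,Fujian,0.006,0.007,0.027,0.049,0.244,0.020,0.085,0.076,0.024,0.030,0.025,0.343,1.300,0.132
S17,Fujian,0.007,0.008,0.070,0.057,0.141,0.014,ND,0.079,0.031,0.061,0.024,0.246,1.459,0.127
S18,Fujian,0.007,0.009,0.045,0.048,0.153,0.013,0.081,0.080,0.032,0.062,0.021,0.238,1.452,0.095
S19,Fujian,0.006,0.006,0.022,0.043,0.114,0.014,0.083,0.069,0.047,0.054,0.027,0.104,1.273,0.133
S20,Fujian,0.005,0.007,0.024,0.048,0.099,0.018,0.083,0.082,0.024,0.029,0.022,0.333,1.569,0.122
S21,Fujian,0.007,0.008,0.044,0.049,0.153,0.013,0.082,0.080,0.032,0.062,0.022,0.237,1.451,0.095
S22,Sichuan,0.011,0.008,0.207,0.184,0.202,0.013,0.085,0.802,0.115,0.543,0.038,0.905,1.418,0.163
S23,Sichuan,0.010,0.007,0.145,0.184,0.138,0.013,0.079,0.594,0.111,0.803,0.035,1.208,2.002,0.138
S24,Sichuan,0.009,0.007,0.137,0.213,0.131,0.013,0.079,0.568,0.105,0.807,0.032,1.232,2.032,0.166
S25,Sichuan,0.011,0.006,0.128,0.182,0.174,0.012,0.089,0.595,0.105,0.110,0.031,1.086,1.465,0.104
S26,Sichuan,0.008,0.006,0.108,0.131,0.065,0.017,ND,0.594,0.035,0.102,0.022,0.784,1.438,0.109
S27,Sichuan,0.010,0.008,0.077,0.156,0.069,0.013,0.082,0.567,0.102,0.279,0.025,0.740,1.163,0.104
S28,Sichuan,0.012,0.009,0.034,0.211,0.143,0.012,ND,0.756,0.107,0.271,0.026,1.016,1.217,0.061
S29,Sichuan,0.015,0.011,0.069,0.221,0.241,0.013,0.081,0.707,0.114,0.297,0.029,0.525,1.513,0.123
S30,Sichuan,0.012,0.007,0.104,0.118,0.114,0.016,ND,0.445,0.047,0.104,0.024,0.663,1.821,0.052
S31,Sichuan,0.012,0.010,0.073,0.109,0.182,0.015,0.090,0.491,0.062,0.155,0.021,0.912,1.131,0.072
S32,Sichuan,0.010,0.009,0.206,0.184,0.202,0.014,0.085,0.802,0.114,0.544,0.038,0.906,1.419,0.164
S33,Sichuan,0.011,0.010,0.145,0.185,0.138,0.013,0.079,0.594,0.111,0.803,0.035,1.208,2.001,0.139
S34,Sichuan,0.009,0.008,0.138,0.213,0.131,0.014,0.081,0.568,0.105,0.807,0.032,1.231,2.032,0.166
S35,Sichuan,0.011,0.010,0.128,0.183,0.174,0.012,0.089,0.596,0.105,0.111,0.031,1.086,1.465,0.104
S36,Sichuan,0.009,0.007,0.108,0.131,0.065,0.017,ND,0.594,0.035,0.102,0.023,0.784,1.439,0.109
S37,Sichuan,0.010,0.008,0.078,0.156,0.069,0.014,0.082,0.567,0.103,0.279,0.025,0.741,1.663,0.105
S38,Sichuan,0.011,0.009,0.034,0.212,0.144,0.012,ND,0.757,0.107,0.271,0.026,1.016,1.217,0.061
S39,Sichuan,0.015,0.011,0.069,0.221,0.241,0.013,0.081,0.707,0.114,0.297,0.029,0.525,1.513,0.123
S40,Sichuan,0.012,0.007,0.105,0.118,0.114,0.016,ND,0.446,0.048,0.105,0.024,0.663,1.522,0.053
S41,Sichuan,0.013,0.011,0.073,0.109,0.183,0.015,0.091,0.491,0.062,0.155,0.021,0.913,1.131,0.072
S42,Sichuan,0.008,0.007,0.109,0.132,0.065,0.017,ND,0.595,0.036,0.103,0.023,0.784,1.438,0.109
S43,Sichuan,0.010,0.008,0.077,0.156,0.069,0.014,0.082,0.567,0.102,0.279,0.025,0.741,1.164,0.105
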