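model_id,purpose,C,P_t,D_t,R,H_t,J,CI,dim1_score,dim12_distance
PROT5,protection,0.633,-0.031,0.124,0.000,1.200,0.523,2.449,-1.729,1.729
PROT1,protection,0.924,0.009,0.081,0.000,0.527,1.000,2.541,-1.699,2.276
PROT3,protection,0.649,0.108,0.129,0.000,0.527,1.000,2.413,-1.438,1.697
PROT2,protection,0.922,-0.026,0.026,0.002,1.780,0.815,3.519,-1.412,1.853
PROT6,protection,0.262,0.103,0.116,0.001,1.480,0.675,2.637,-1.223,1.311
PROD1,production,0.145,0.369,0.249,0.011,1.560,0.450,2.784,-0.716,1.696
PROD2,production,0.193,0.394,0.260,0.012,1.620,0.478,2.957,-0.612,1.560
PROT4,protection,0.761,0.398,0.213,0.001,1.550,0.665,3.588,-0.550,0.552
PROD7,production,0.815,0.648,0.352,0.000,1.220,0.412,3.447,-0.193,0.963
PROD4,production,0.221,0.520,0.357,0.066,1.970,0.593,3.727,0.089,1.323
PROD5,production,0.564,0.611,0.497,0.000,0.527,1.000,3.199,0.225,0.295
BIOM3,biomimicry,0.382,0.270,0.203,0.658,2.430,0.881,4.824,0.368,0.542
PROD6,production,0.676,0.608,0.359,0.000,1.760,0.994,4.397,0.499,0.520
BIOM1,biomimicry,0.633,0.362,0.210,0.672,2.440,0.889,5.206,0.598,0.934
BIOM2,biomimicry,0.310,0.369,0.246,0.694,2.470,0.904,4.993,0.677,0.708
BIOM4,biomimicry,0.311,0.388,0.246,0.700,2.480,0.907,5.032,0.744,0.766
PROD3,production,0.430,0.721,0.529,0.064,2.200,0.736,4.680,1.034,1.476
BIOM7,biomimicry,0.624,0.451,0.304,0.539,2.500,0.988,5.406,1.035,1.193
BIOM5,biomimicry,0.646,0.578,0.390,0.839,2.590,0.995,6.038,1.682,1.802
BIOM6,biomimicry,0.828,0.765,0.482,0.905,2.600,0.997,6.577,2.623,2.674
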