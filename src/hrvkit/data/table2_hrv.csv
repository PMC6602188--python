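subject_id,mean_ibi_off,mean_ibi_on,hr_off,hr_on,nlf_off,nlf_on,nhf_off,nhf_on,rlfhf_off,rlfhf_on
A1,866.2,1001.2,70.5,60.2,0.393,0.460,0.607,0.540,0.648,0.853
A2,938.7,1062.1,64.0,56.5,0.476,0.277,0.524,0.723,0.909,0.383
A3,874.3,845.4,68.7,71.1,0.783,0.630,0.217,0.370,3.614,1.704
A4,1137.4,1158.4,52.8,51.9,0.514,0.323,0.486,0.677,1.057,0.477
A5,996.4,1098.1,60.4,55.1,0.436,0.149,0.564,0.851,0.772,0.175
A6,996.6,767.0,60.3,78.4,0.861,0.867,0.139,0.133,6.180,6.525
A7,1082.6,1109.8,55.5,54.2,0.253,0.243,0.747,0.757,0.339,0.322
A8,622.1,674.0,98.7,89.1,0.991,0.751,0.009,0.249,105.366,3.011
A9,847.3,915.4,71.0,65.6,0.696,0.547,0.304,0.453,2.292,1.206
A10,627.1,649.3,95.7,92.4,0.804,0.658,0.196,0.342,4.091,1.922
A11,893.8,971.2,67.2,61.9,0.488,0.278,0.512,0.722,0.952,0.385
A12,916.1,980.9,65.9,61.2,0.796,0.860,0.204,0.140,3.912,6.136
A13,837.0,884.3,72.0,68.0,0.625,0.618,0.375,0.382,1.666,1.619
A14,911.4,969.5,65.9,61.9,0.340,0.270,0.660,0.730,0.515,0.370
A15,933.1,1062.7,64.4,56.6,0.468,0.322,0.532,0.678,0.880,0.474
A16,1030.8,1155.7,58.5,51.4,0.542,0.558,0.458,0.442,1.182,1.263
A17,1154.4,1176.4,53.4,51.1,0.983,0.490,0.017,0.510,58.095,0.960
A18,697.8,729.2,86.2,82.4,0.654,0.688,0.346,0.312,1.888,2.210
A19,959.7,1087.2,62.6,55.3,0.555,0.318,0.445,0.682,1.248,0.466
A20,1156.0,1146.0,52.0,52.4,0.477,0.203,0.523,0.797,0.913,0.254
A21,649.6,755.5,92.4,82.4,0.688,0.990,0.312,0.010,2.205,97.634
A22,893.3,883.2,67.2,68.0,0.627,0.588,0.373,0.412,1.681,1.425
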