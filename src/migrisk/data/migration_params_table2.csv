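food,compound,alpha,k_pf,d_cm2_s,r_squared
Eastern leaf,TPhP,0.328,762.51,8.00e-11,0.845
Eastern leaf,EHDPP,0.033,7681.78,9.59e-11,0.93
Eastern leaf,TBOEP,1.713,145.98,8.84e-11,0.896
Eastern leaf,TnBP,0.194,1290.98,5.16e-11,0.914
Eastern leaf,TPPO,3.293,75.92,9.53e-11,0.928
Jasmine tea,TPhP,0.288,868.58,8.65e-11,0.928
Jasmine tea,EHDPP,0.036,7044.28,9.70e-11,0.933
Jasmine tea,TBOEP,1.33,187.98,8.77e-11,0.929
Jasmine tea,TnBP,0.159,1568.98,2.56e-11,0.897
Jasmine tea,TPPO,2.584,96.74,9.30e-11,0.973
Soda water,TPhP,0.273,915.29,8.52e-11,0.96
Soda water,EHDPP,0.033,7574.96,9.25e-11,0.975
Soda water,TBOEP,1.537,162.68,8.81e-11,0.956
Soda water,TnBP,0.204,1222.76,5.66e-11,0.949
Soda water,TPPO,3.142,79.56,9.54e-11,0.951
Vinegar,TPhP,0.309,803.3,8.99e-11,0.924
Vinegar,EHDPP,0.034,7098.21,1.07e-10,0.976
Vinegar,TBOEP,1.538,162.53,8.92e-11,0.908
Vinegar,TnBP,0.252,991.45,5.46e-11,0.931
Vinegar,TPPO,3.462,72.21,9.48e-11,0.976
Beer,TPhP,0.353,708.45,8.95e-11,0.858
Beer,EHDPP,0.044,5681.07,8.84e-11,0.893
Beer,TBOEP,1.803,138.69,8.07e-11,0.931
Beer,TnBP,0.206,1212.84,5.48e-11,0.944
Beer,TPPO,4.013,62.3,9.26e-11,0.975
Cooking wine,TPhP,0.453,552.05,7.04e-11,0.98
Cooking wine,EHDPP,0.05,5024.95,9.10e-11,0.871
Cooking wine,TBOEP,3.46,72.25,6.86e-11,0.919
Cooking wine,TnBP,0.286,874.1,4.86e-11,0.919
Cooking wine,TPPO,5.831,42.88,9.14e-11,0.96
Soy milk,TPhP,0.771,324.39,7.67e-11,0.923
Soy milk,EHDPP,0.141,1768.35,7.39e-11,0.956
Soy milk,TBOEP,3.135,79.76,8.41e-11,0.979
Soy milk,TnBP,0.338,739.06,3.98e-11,0.94
Soy milk,TPPO,3.732,66.98,8.84e-11,0.961
Baijiu,TPhP,1.541,162.21,3.61e-11,0.889
Baijiu,EHDPP,0.21,1189.25,6.50e-11,0.875
Baijiu,TBOEP,5.724,43.68,4.71e-11,0.92
Baijiu,TnBP,0.531,470.65,5.35e-11,0.917
Baijiu,TPPO,10.088,24.78,7.57e-11,0.899
Coconut milk,TPhP,0.86,290.6,6.76e-11,0.949
Coconut milk,EHDPP,0.118,2122.44,8.35e-11,0.827
Coconut milk,TBOEP,2.623,95.31,8.87e-11,0.948
Coconut milk,TnBP,0.417,599.53,2.23e-11,0.881
Coconut milk,TPPO,3.868,64.63,9.18e-11,0.897
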