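food,scenario,compound,edi_ng_kg_bw_day,hq_printed
Eastern leaf,median,TPhP,96.79,1.38e-3
Eastern leaf,median,EHDPP,0.85,1.41e-4
Eastern leaf,median,TBOEP,905.78,6.04e-2
Eastern leaf,median,TnBP,194.25,1.94e-2
Eastern leaf,median,TPPO,1278.44,6.39e-2
Jasmine tea,median,TPhP,85.23,1.22e-3
Jasmine tea,median,EHDPP,1.20,2.00e-4
Jasmine tea,median,TBOEP,802.16,5.35e-2
Jasmine tea,median,TnBP,165.29,1.65e-2
Jasmine tea,median,TPPO,1284.33,6.42e-2
Soda water,median,TPhP,74.49,1.06e-4
Soda water,median,EHDPP,1.10,1.83e-4
Soda water,median,TBOEP,890.12,5.93e-2
Soda water,median,TnBP,217.73,2.18e-2
Soda water,median,TPPO,1312.87,6.56e-2
Vinegar,median,TPhP,145.08,1.82e-5
Vinegar,median,EHDPP,9.61,2.55e-6
Vinegar,median,TBOEP,538.78,6.46e-4
Vinegar,median,TnBP,152.67,3.13e-4
Vinegar,median,TPPO,557.34,6.40e-4
Beer,median,TPhP,16.16,9.34e-4
Beer,median,EHDPP,0.40,1.52e-4
Beer,median,TBOEP,96.87,4.24e-2
Beer,median,TnBP,35.38,1.54e-2
Beer,median,TPPO,134.47,5.33e-2
Cooking wine,median,TPhP,173.26,3.97e-5
Cooking wine,median,EHDPP,8.05,6.58e-6
Cooking wine,median,TBOEP,499.07,1.91e-3
Cooking wine,median,TnBP,190.69,7.50e-4
Cooking wine,median,TPPO,518.62,1.95e-3
Soy milk,median,TPhP,1.27,2.07e-3
Soy milk,median,EHDPP,0.02,1.60e-3
Soy milk,median,TBOEP,9.70,3.59e-2
Soy milk,median,TnBP,3.13,1.53e-2
Soy milk,median,TPPO,12.80,2.79e-2
Baijiu,median,TPhP,65.37,2.31e-4
Baijiu,median,EHDPP,0.91,6.60e-5
Baijiu,median,TBOEP,635.47,6.46e-3
Baijiu,median,TnBP,153.81,3.54e-3
Baijiu,median,TPPO,1066.29,6.72e-3
Coconut milk,median,TPhP,2.78,2.48e-3
Coconut milk,median,EHDPP,0.04,1.34e-3
Coconut milk,median,TBOEP,28.60,3.33e-2
Coconut milk,median,TnBP,7.50,1.91e-2
Coconut milk,median,TPPO,38.92,2.59e-2
Eastern leaf,p95,TPhP,241.97,3.46e-3
Eastern leaf,p95,EHDPP,2.12,3.54e-4
Eastern leaf,p95,TBOEP,2264.44,1.51e-1
Eastern leaf,p95,TnBP,485.62,4.86e-2
Eastern leaf,p95,TPPO,3196.10,1.60e-1
Jasmine tea,p95,TPhP,213.07,3.04e-3
Jasmine tea,p95,EHDPP,2.99,4.99e-4
Jasmine tea,p95,TBOEP,2005.41,1.34e-1
Jasmine tea,p95,TnBP,413.24,4.13e-2
Jasmine tea,p95,TPPO,3210.82,1.61e-1
Soda water,p95,TPhP,186.22,2.66e-3
Soda water,p95,EHDPP,2.75,4.58e-4
Soda water,p95,TBOEP,2225.31,1.48e-1
Soda water,p95,TnBP,544.33,5.44e-2
Soda water,p95,TPPO,3282.18,1.64e-1
Vinegar,p95,TPhP,435.24,7.28e-5
Vinegar,p95,EHDPP,28.84,1.02e-5
Vinegar,p95,TBOEP,1616.35,2.59e-3
Vinegar,p95,TnBP,458.01,1.25e-3
Vinegar,p95,TPPO,1672.01,2.56e-3
Beer,p95,TPhP,48.47,3.11e-3
Beer,p95,EHDPP,1.19,5.06e-4
Beer,p95,TBOEP,290.62,1.41e-1
Beer,p95,TnBP,106.15,5.13e-2
Beer,p95,TPPO,403.41,1.78e-1
Cooking wine,p95,TPhP,519.79,1.19e-4
Cooking wine,p95,EHDPP,24.15,1.97e-5
Cooking wine,p95,TBOEP,1497.20,5.72e-3
Cooking wine,p95,TnBP,572.08,2.25e-3
Cooking wine,p95,TPPO,1555.85,5.84e-3
Soy milk,p95,TPhP,5.10,6.22e-3
Soy milk,p95,EHDPP,0.06,4.81e-3
Soy milk,p95,TBOEP,38.78,1.08e-1
Soy milk,p95,TnBP,12.54,4.58e-2
Soy milk,p95,TPPO,51.21,8.36e-2
Baijiu,p95,TPhP,217.89,6.92e-4
Baijiu,p95,EHDPP,3.03,1.98e-4
Baijiu,p95,TBOEP,2118.22,1.94e-2
Baijiu,p95,TnBP,512.70,1.06e-2
Baijiu,p95,TPPO,3554.31,2.02e-2
Coconut milk,p95,TPhP,8.33,7.43e-3
Coconut milk,p95,EHDPP,0.12,4.03e-3
Coconut milk,p95,TBOEP,85.80,9.98e-2
Coconut milk,p95,TnBP,22.51,5.72e-2
Coconut milk,p95,TPPO,116.77,7.78e-2
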