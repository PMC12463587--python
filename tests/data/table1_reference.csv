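section,name,base,low,high,distribution
china.prices,ramucirumab,5.2322,4.186,6.279,gamma
china.prices,paclitaxel,0.28,0.224,0.335,gamma
china.prices,ondansetron,0.36,0.288,0.433,gamma
china.prices,dexamethasone,0.018,0.0148,0.0221,gamma
china.prices,diphenhydramine,0.103,0.0823,0.123,gamma
china.prices,capecitabine,0.000653,0.000522,0.000783,gamma
china.prices,calcium_folinate,0.0355,0.0284,0.0426,gamma
china.prices,oxaliplatin,0.881,0.705,1.058,gamma
china.prices,fluorouracil,0.0183,0.0146,0.022,gamma
china.prices,irinotecan,0.0955,0.0764,0.115,gamma
china.care,enhanced_ct,23.693,10.659,106.647,gamma
china.care,blood_biochemistry,63.814,33.253,93.564,gamma
china.care,blood_routine,1.93,1.425,3.622,gamma
china.care,urine_routine,0.594,0.287,2.553,gamma
china.care,injection_administration,0.802,0.158,0.643,gamma
china.care,intravenous_injection,0.713,0.356,1.564,gamma
china.care,terminal_care,1506.51,1205.21,1807.81,gamma
china.care,bsc_per_cycle,267.78,214.22,321.34,gamma
china.ae_costs,neutropenia,136.792,109.418,164.147,gamma
china.ae_costs,peripheral_neuropathy,1097.008,877.607,1316.41,gamma
china.ae_costs,hypertension,17.824,14.261,21.387,gamma
china,weight,69.0,55.2,82.88,gamma
china,bsa,1.74,1.392,2.088,gamma
china,discount,0.05,0.0,0.08,fixed
china,wtp,38042.49,,,fixed
us.prices,ramucirumab,15.0,12.0,18.0,gamma
us.prices,paclitaxel,0.2882,0.23056,0.34584,gamma
us.prices,ondansetron,0.1056,0.08448,0.12672,gamma
us.prices,dexamethasone,0.02255,0.01804,0.02706,gamma
us.prices,diphenhydramine,0.0602,0.04816,0.07224,gamma
us.prices,capecitabine,0.002,0.0016,0.0024,gamma
us.prices,calcium_folinate,0.07026,0.056208,0.084312,gamma
us.prices,oxaliplatin,0.6,0.48,0.72,gamma
us.prices,fluorouracil,0.01027,0.008216,0.012324,gamma
us.prices,irinotecan,0.3,0.24,0.36,gamma
us.care,enhanced_ct,530.79,424.63,636.95,gamma
us.care,blood_biochemistry,10.56,8.45,12.67,gamma
us.care,blood_routine,7.77,6.22,9.32,gamma
us.care,urine_routine,3.17,2.54,3.8,gamma
us.care,injection_administration,13.91,11.13,16.69,gamma
us.care,intravenous_injection,223.3,178.64,267.96,gamma
us.care,terminal_care,19247.03,15397.62,23096.44,gamma
us.care,bsc_per_cycle,2262.59,1810.07,2715.11,gamma
us.ae_costs,neutropenia,18360.82,14688.66,22032.98,gamma
us.ae_costs,peripheral_neuropathy,14184.2,11347.36,17021.04,gamma
us.ae_costs,hypertension,19272.01,15417.61,23126.41,gamma
us,weight,75.0,60.0,90.0,gamma
us,bsa,1.8,1.44,2.16,gamma
us,discount,0.03,0.0,0.08,fixed
us,wtp,150000.0,,,fixed
utilities,pfs,0.797,0.64,0.96,beta
utilities,pd,0.577,0.46,0.69,beta
ae_disutility,neutropenia,0.2,0.16,0.24,beta
ae_disutility,peripheral_neuropathy,0.16,0.128,0.192,beta
ae_disutility,hypertension,0.04,0.032,0.048,beta
ae_incidence_switch,neutropenia,0.2624,0.2099,0.3149,beta
ae_incidence_switch,peripheral_neuropathy,0.06,0.048,0.072,beta
ae_incidence_switch,hypertension,0.06,0.048,0.072,beta
ae_incidence_control,neutropenia,0.0963,0.077,0.1156,beta
ae_incidence_control,peripheral_neuropathy,0.07,0.056,0.084,beta
survival.overall.os_switch,loglogistic.shape,2.309,,,fixed
survival.overall.os_switch,loglogistic.scale,13.051,,,fixed
survival.overall.os_control,loglogistic.shape,1.891,,,fixed
survival.overall.os_control,loglogistic.scale,9.593,,,fixed
survival.overall.pfs_switch,loglogistic.shape,2.061,,,fixed
survival.overall.pfs_switch,loglogistic.scale,6.767,,,fixed
survival.overall.pfs_control,loglogistic.shape,1.697,,,fixed
survival.overall.pfs_control,loglogistic.scale,3.579,,,fixed
survival.cps_ge5.os_switch,loglogistic.shape,2.386,,,fixed
survival.cps_ge5.os_switch,loglogistic.scale,15.518,,,fixed
survival.cps_ge5.os_control,lognormal.meanlog,2.376,,,fixed
survival.cps_ge5.os_control,lognormal.sdlog,0.805,,,fixed
survival.cps_ge5.pfs_switch,lognormal.meanlog,2.0989,,,fixed
survival.cps_ge5.pfs_switch,lognormal.sdlog,0.7146,,,fixed
survival.cps_ge5.pfs_control,lognormal.meanlog,1.802,,,fixed
survival.cps_ge5.pfs_control,lognormal.sdlog,0.856,,,fixed
subsequent_fraction,switch,0.58,,,fixed
subsequent_fraction,control,0.56,,,fixed
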