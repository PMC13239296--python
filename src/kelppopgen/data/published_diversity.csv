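population,cohort,age_months,n,subset,PL_pct,AR,PA_pct,Ho,He,FIS
warm,wild,all,98,neutral,36.626,1.038,20.975,0.005,0.006,0.200
warm,hatchery,all,62,neutral,17.960,,3.784,0.004,0.006,0.183
warm,hatchery,5,12,neutral,29.787,1.026,0.449,0.003,0.005,0.250
warm,hatchery,7,33,neutral,35.106,1.029,1.860,0.004,0.005,0.174
warm,hatchery,9,17,neutral,38.830,1.037,1.155,0.004,0.006,0.366
cool,wild,all,101,neutral,54.586,1.090,26.491,0.014,0.017,0.175
cool,hatchery,all,36,neutral,27.646,,3.784,0.011,0.016,0.206
cool,hatchery,5,9,neutral,12.957,1.099,1.347,0.015,0.019,0.226
cool,hatchery,7,18,neutral,16.164,1.078,1.411,0.009,0.015,0.361
cool,hatchery,9,9,neutral,7.633,1.090,1.090,0.008,0.012,0.315
warm,wild,all,98,provenance,62.963,1.369,3.704,0.080,0.095,0.146
warm,hatchery,all,62,provenance,66.667,,0.000,0.051,0.640,0.150
cool,wild,all,101,provenance,70.370,1.408,0.000,0.089,0.103,0.121
cool,hatchery,all,36,provenance,66.667,,0.000,0.064,0.111,0.415
warm,wild,all,98,hatchery,60.000,1.074,0.000,0.011,0.011,-0.005
warm,hatchery,all,62,hatchery,93.333,,20.000,0.127,0.171,0.323
cool,wild,all,101,hatchery,20.000,1.027,0.000,0.004,0.004,-0.005
cool,hatchery,all,36,hatchery,33.333,,0.000,0.008,0.028,0.526
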