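time_h,conc_no_tenside_mg_per_ml,amount_no_tenside_mg,amount_tenside_mg
0,0,0,0
1,0.0715,0.914,1.262
2,0.0855,1.093,1.403
3,0.0780,0.997,1.280
4,0.0735,0.952,1.222
5,0.0490,0.626,0.803
6,0.0535,0.684,0.878
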