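fert_date,treatment,mean_temp_c,temp_sd_c,atu50,atu50_sd,dpf50,dpf50_sd
2016-11-01,A,5.3,0.38,526,3.9,99,0.8
2016-11-04,A,5.3,0.24,526,9.2,100,1.8
2016-11-08,A,5.2,0.15,534,2.7,102,0.5
2016-11-11,A,5.2,0.15,521,1.5,99,0.3
2016-11-01,B,5.2,1.92,534,5.3,100,1.6
2016-11-04,B,5.2,1.90,531,3.0,103,0.9
2016-11-08,B,5.1,1.91,515,2.2,102,0.9
2016-11-11,B,5.2,1.94,501,2.2,101,0.7
2016-11-01,C,3.9,1.40,492,2.9,124,0.8
2016-11-04,C,3.9,1.33,485,6.9,125,2.0
2016-11-08,C,3.8,1.25,471,7.0,124,2.0
2016-11-11,C,3.7,1.24,476,3.8,127,1.1
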