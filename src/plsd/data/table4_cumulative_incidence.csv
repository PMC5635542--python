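# Cumulative incidence from 25 years of age (percent, with symmetric 95% CI)
# for colorectal and extra-colonic cancer by series, sex and attained age,
# with cumulative observation years and first-cancer counts per row.
series,cancer_class,sex,age_stop,obs_years,n_cancers,cum_incidence_pct,ci_low_pct,ci_high_pct
finnish,crc,all,40,1982,19,12.9,7.4,18.3
finnish,crc,all,50,3301,40,25.4,18.6,32.3
finnish,crc,all,60,4070,47,31.7,24.0,39.4
finnish,crc,all,70,4330,51,39.2,29.4,48.9
other,crc,all,40,1299,17,16.4,9.2,23.7
other,crc,all,50,2424,36,30.0,21.7,38.3
other,crc,all,60,2935,48,44.9,34.6,55.2
other,crc,all,70,3094,50,53.8,39.6,68.0
finnish,crc,male,40,1026,12,15.7,7.5,23.9
finnish,crc,male,50,1682,25,30.8,20.7,40.9
finnish,crc,male,60,2075,29,36.9,26.1,47.7
finnish,crc,male,70,2189,30,41.1,28.2,54.0
other,crc,male,40,610,9,18.5,7.2,29.7
other,crc,male,50,1110,21,37.0,24.3,49.8
other,crc,male,60,1288,28,57.8,41.5,74.0
other,crc,male,70,1365,28,57.8,41.5,74.0
finnish,crc,female,40,956,7,9.6,2.8,16.4
finnish,crc,female,50,1623,15,19.4,10.6,28.3
finnish,crc,female,60,2010,18,26.2,15.2,37.2
finnish,crc,female,70,2156,21,36.4,22.1,50.6
other,crc,female,40,689,8,14.8,5.3,24.4
other,crc,female,50,1314,15,24.1,13.4,34.8
other,crc,female,60,1646,20,35.2,22.0,48.3
other,crc,female,70,1729,22,55.3,30.5,80.0
finnish,extracolonic,all,40,1982,4,2.7,0.1,5.3
finnish,extracolonic,all,50,3301,24,16.9,10.7,23.2
finnish,extracolonic,all,60,4070,39,32.2,23.5,40.9
finnish,extracolonic,all,70,4330,42,39.7,28.2,51.2
other,extracolonic,all,40,1299,3,2.9,0.0,6.1
other,extracolonic,all,50,2424,22,17.8,11.0,24.6
other,extracolonic,all,60,2934,35,35.3,24.8,45.7
other,extracolonic,all,70,3094,41,57.2,41.0,73.5
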