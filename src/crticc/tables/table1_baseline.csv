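cluster_id,arm,n,age_mean,age_sd,male_pct,nyha2_pct,nyha3_pct,nyha4_pct,ht_pct,cm_pct
CP 1,CP,30,,,,6.7,40.0,53.3,,
CP 2,CP,30,80.50,8.32,56.7,3.3,56.7,40.0,66.7,20.0
CP 3,CP,31,79.39,9.32,48.4,12.9,58.1,29.0,71.0,29.0
CP 4,CP,30,82.00,7.49,46.7,6.7,63.3,30.0,73.3,30.0
CP 5,CP,31,82.13,8.54,41.9,3.2,71.0,25.8,64.5,29.0
CP 6,CP,31,83.39,7.32,48.4,16.1,54.8,29.0,71.0,19.4
CP 7,CP,31,82.29,7.00,51.6,3.2,41.9,54.8,80.6,29.0
UC 8,UC,30,81.43,8.61,50.0,6.7,46.7,46.7,83.3,50.0
UC 9,UC,30,78.77,10.08,53.3,3.3,50.0,46.7,83.3,43.3
UC 10,UC,32,78.94,9.61,46.9,0.0,56.3,43.8,71.9,43.8
UC 11,UC,31,76.23,8.09,51.6,6.5,51.6,41.9,74.2,38.7
UC 12,UC,30,80.53,7.32,53.3,6.7,40.0,53.3,86.7,43.3
UC 13,UC,30,82.60,7.74,40.0,10.0,50.0,40.0,86.7,40.0
UC 14,UC,32,79.22,6.48,62.5,15.6,75.0,9.4,40.6,9.4
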