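cluster_id,arm,n,los_mean,los_sd,cost_mean,cost_sd,dnyha2_pct,dnyha3_pct,dnyha4_pct,mortality_pct,aos_pct,ur_pct
CP 1,CP,30,10.97,5.44,2227.30,591.83,42.9,53.6,3.6,6.7,96.7,6.7
CP 2,CP,30,13.13,5.94,2171.77,470.22,39.3,57.1,3.6,3.3,73.3,0.0
CP 3,CP,31,9.13,4.33,2077.87,550.71,48.3,51.7,0.0,6.5,77.4,9.7
CP 4,CP,30,8.27,4.82,2113.47,550.89,46.4,50.0,3.6,6.7,73.3,13.3
CP 5,CP,31,10.35,4.72,2089.52,482.24,31.0,65.5,3.4,6.5,58.1,6.5
CP 6,CP,31,9.48,4.86,1969.10,571.62,50.0,46.7,3.3,3.2,64.5,16.1
CP 7,CP,31,11.13,4.98,2234.29,489.18,31.0,65.5,3.4,6.5,90.3,3.2
UC 8,UC,30,12.33,7.63,2207.53,591.92,24.0,64.0,12.0,16.7,83.3,13.3
UC 9,UC,30,10.93,6.11,2322.50,488.25,45.5,40.9,13.6,20.0,76.7,10.0
UC 10,UC,32,10.13,5.83,2290.13,525.57,23.1,61.5,15.4,15.6,78.1,12.5
UC 11,UC,31,11.26,6.00,2243.74,480.45,11.1,74.1,14.8,12.9,77.4,16.1
UC 12,UC,30,9.43,6.13,2380.37,719.91,8.0,84.0,8.0,16.7,90.0,20.0
UC 13,UC,30,11.70,6.82,2150.43,613.75,25.9,66.7,7.4,10.0,76.7,23.3
UC 14,UC,32,14.06,7.65,1898.31,490.99,77.8,22.2,0.0,15.6,25.0,3.1
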