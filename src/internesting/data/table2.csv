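tag,start,end,occupancy_days,bandwidth,site_fidelity,area50_km2,area95_km2,centroid_depth_m,centroid_to_shore_km
106360,2011-06-07,2011-08-04,58,0.64,Pass,86.6,257.2,11.0,3.8
53016,2012-06-05,2012-07-17,42,0.24,Pass,35.5,287.6,9.0,1.2
53000,2012-06-08,2012-07-24,46,0.31,Pass,50.6,225.0,10.0,3.8
53164,2012-06-08,2012-07-14,36,0.3,Pass,18.1,107.9,5.0,0.9
119947,2012-06-13,2012-08-12,60,0.17,Pass,36.5,157.8,13.0,9.3
53000,2012-07-28,2012-08-27,30,0.53,Pass,108.2,465.7,95.0,67.1
108172,2011-08-11,2011-08-31,20,0.25,Pass,76.7,354.6,67.0,68.0
119923,2012-07-31,2012-08-31,31,0.83,Pass,54.1,217.7,37.0,113.6
119924,2012-07-16,2012-08-31,46,0.18,Pass,88.7,432.6,37.0,36.2
119944,2012-06-28,2012-08-29,62,0.94,Pass,63.5,250.1,32.0,25.9
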