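tag,site,ccl_cm,tracking_days,internesting_days,encounters,mean_interval_d,mean_distance_km,n_distances,tdm_km,tdm_per_day_km
108170,AL,95.2,86,,1,,,0,,
106360,AL,92.3,85,58,3,22.5,7.1,2,836.0,14.4
108172,AL,93.9,84,84,3,22,129.0,2,2683.4,31.9
106345,AL,90.1,83,83,2,42,3.5,2,2163.4,26.1
108171,AL,90.4,83,,1,,,0,,
106337,AL,93.6,81,81,3,21.5,8.7,2,1800.0,22.2
108173,AL,95.9,81,,1,,,0,,
108174,AL,88.0,28,,1,,,0,,
106358,AL,92.5,78,,1,,,0,,
106361,AL,92.0,77,,1,,,0,,
108961,AL,91.5,39,,1,,,0,,
108964,AL,94.6,32,,1,,,0,,
108965,AL,87.0,31,,1,,,0,,
119940,AL,94.2,68,67,3,19.5,13.0,2,2619.3,39.1
119941,AL,92.0,86,23,2,19,118.7,1,2110.3,39.8
119943,AL,97.5,88,86,1,,,0,2230.4,25.9
119938,AL,97.5,88,,1,,,0,,
119924,AL,95.4,87,86,2,12,7.8,1,2897.8,33.7
119944,AL,90.8,85,83,1,,,0,1324.6,16.0
119946,AL,95.0,83,81,2,13,254.6,1,1220.4,15.1
119945,AL,98.9,60,,1,,,0,,
119947,AL,98.5,60,60,1,,,0,725.1,12.1
119923,AL,95.6,79,79,2,12,12.9,1,2491.1,31.5
57656,SJP,99.5,36,,2,24,1.7,1,,
89971,SJP,103.2,35,,5,14,2.2,4,,
47755,SJP,97.2,28,,3,12,0.2,2,,
52968,SJP,90.0,27,,1,,,0,,
53017,SJP,88.0,26,23,2,26,2.0,1,293.1,12.7
53016,SJP,102.0,67,43,4,13,4.4,3,515.4,12.0
53000,SJP,102.0,80,80,1,,,0,1638.7,20.5
53164,SJP,102.0,43,36,5,11.8,2.4,4,220.8,6.1
119942,SJP,82.4,82,82,3,21,1.4,2,2221.0,27.1
119950,SJP,102.0,56,55,4,17.3,3.0,3,540.4,9.8
119949,SJP,100.0,40,31,4,13,1.7,3,399.4,12.9
119951,SJP,103.3,52,37,1,,,0,422.0,11.4
119948,SJP,92.5,81,,5,12.8,1.7,4,,
119952a,SJP,101.1,23,23,2,23,402.1,1,653.3,28.4
119952,SJP,90.1,39,37,3,11.5,1.8,2,752.5,20.3
120438,EAFB,97.0,52,52,1,,,0,2837.3,54.6
120439,EAFB,102.5,51,22,2,22,54.8,1,531.7,24.2
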