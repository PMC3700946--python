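tag,site,internesting_days,n_centroids,d12_km,d23_km,d34_km,total_km
108172,AL,84,2,726.8,,,726.8
106345,AL,83,3,31.0,206.2,,237.2
106337,AL,81,4,31.5,20.2,196.60,248.3
119943,AL,86,3,82.6,355.0,,437.6
119924,AL,86,3,7.7,70.9,,78.6
119944,AL,83,2,236.9,,,236.9
119946,AL,81,2,345.0,,,345.0
119923,AL,79,2,394.1,,,394.1
53000,SJP,80,2,94.0,,,94.0
119942,SJP,82,2,348.8,,,348.8
119952,SJP,37,2,199.8,,,199.8
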