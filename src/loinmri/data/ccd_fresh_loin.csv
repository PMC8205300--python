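run,te_coded,tr_coded,te_ms,tr_ms,r_aw,r_ph,r_moisture,r_lipids,r_colorL
1,1,1,26,910,0.958,0.864,0.881,0.953,0.822
2,0,0,22,770,0.988,0.916,0.972,0.987,0.950
3,0,0,22,770,0.977,0.943,0.970,0.977,0.960
4,0,0,22,770,0.982,0.968,0.969,0.980,0.957
5,0,-1,22,630,0.980,0.962,0.965,0.979,0.958
6,0,1,22,910,0.983,0.967,0.969,0.982,0.962
7,-1,0,18,770,0.982,0.888,0.936,0.979,0.900
8,1,-1,26,630,0.976,0.970,0.966,0.975,0.962
9,-1,1,18,910,0.976,0.965,0.952,0.975,0.945
10,0,0,22,770,0.975,0.958,0.961,0.974,0.954
11,1,0,26,770,0.965,0.945,0.931,0.962,0.920
12,0,0,22,770,0.970,0.963,0.960,0.968,0.956
13,-1,-1,18,630,0.974,0.911,0.942,0.971,0.922
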