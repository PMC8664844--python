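g,R,Cutoff,ACC,Sn,Sp,MCC,AUC
0,0.650,418,0.883,0.878,0.887,0.766,0.926
1,0.592,420,0.872,0.879,0.865,0.744,0.918
2,0.634,414,0.867,0.865,0.868,0.734,0.919
3,0.653,412,0.869,0.864,0.874,0.739,0.916
4,0.602,417,0.865,0.867,0.862,0.730,0.918
5,0.601,416,0.867,0.873,0.861,0.735,0.918
6,0.601,407,0.865,0.862,0.868,0.730,0.913
7,0.664,415,0.862,0.885,0.840,0.726,0.911
8,0.668,415,0.862,0.848,0.875,0.724,0.912
9,0.585,425,0.861,0.885,0.837,0.724,0.909
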