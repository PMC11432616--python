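subject,patient,phase,observer1,observer2
1,1,pre,117.13,117.25
2,2,pre,102.01,103.43
3,3,pre,114.05,113.62
4,4,pre,109.97,108.05
5,5,pre,125.32,121.00
6,1,post,128.60,126.18
7,2,post,106.10,106.75
8,3,post,111.43,107.83
9,4,post,107.10,111.20
10,5,post,125.70,124.50
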