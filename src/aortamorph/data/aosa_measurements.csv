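patient,pathology,aosa_pre_mean,aosa_pre_sd,aosa_post_mean,aosa_post_sd,percent_change,cv_pre,cv_post
1,aneurysm,117.25,1.32,126.18,1.00,7.07,1.12,0.80
2,aneurysm,103.15,1.35,106.75,0.95,3.50,1.35,0.95
3,dissection,113.62,0.96,107.83,1.45,-5.10,0.96,1.45
4,aneurysm,108.05,1.23,111.20,0.99,2.91,1.14,0.89
5,aneurysm,121.00,1.52,124.50,1.26,2.89,1.26,1.00
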