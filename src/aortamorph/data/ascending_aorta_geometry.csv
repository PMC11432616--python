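patient,phase,aai_mean,aai_sd,diameter,tortuosity,centerline_length,outer_line,inner_line
1,pre,10.95,0.84,37.10,0.07,62.37,90.42,42.81
2,pre,10.54,0.45,32.67,0.21,80.92,108.56,56.75
3,pre,16.61,0.68,31.77,0.09,70.78,95.06,53.24
4,pre,18.60,1.02,34.83,0.14,90.61,115.73,69.50
5,pre,12.55,1.31,40.03,0.09,75.10,101.30,55.46
1,post,15.74,0.97,37.72,0.07,65.51,94.62,44.80
2,post,14.57,0.35,31.29,0.17,79.18,110.60,57.38
3,post,6.52,1.87,32.40,0.11,72.32,96.32,55.63
4,post,16.86,0.91,34.91,0.17,93.88,122.03,72.27
5,post,8.44,1.42,40.98,0.10,74.51,105.00,61.67
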