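# Published per-participant total functional minutes and fraction of the session
# functionally active, per arm side and estimation method (ground_truth = video
# annotation, mlm = epoch-feature classifier, counts = counts-threshold baseline),
# for the ten-participant home-monitoring validation cohort (fixture v1).
# Printed mean differences vs ground truth: mlm 0.14 [0.04] left / 0.10 [0.04] right;
# counts 0.27 [0.07] left / 0.24 [0.07] right.
participant,side,method,minutes,percent
P_001,left,ground_truth,15.93,0.56
P_001,left,mlm,19.73,0.69
P_001,left,counts,26.28,0.92
P_002,left,ground_truth,12.33,0.69
P_002,left,mlm,15.47,0.87
P_002,left,counts,16.60,0.93
P_003,left,ground_truth,21.87,0.79
P_003,left,mlm,24.27,0.87
P_003,left,counts,26.88,0.97
P_004,left,ground_truth,19.73,0.66
P_004,left,mlm,23.80,0.80
P_004,left,counts,28.43,0.95
P_005,left,ground_truth,12.53,0.71
P_005,left,mlm,16.53,0.94
P_005,left,counts,17.05,0.97
P_006,left,ground_truth,12.20,0.58
P_006,left,mlm,15.13,0.72
P_006,left,counts,20.27,0.96
P_007,left,ground_truth,10.40,0.66
P_007,left,mlm,12.33,0.78
P_007,left,counts,15.15,0.96
P_008,left,ground_truth,16.07,0.75
P_008,left,mlm,20.07,0.94
P_008,left,counts,19.77,0.93
P_009,left,ground_truth,15.40,0.71
P_009,left,mlm,17.47,0.80
P_009,left,counts,20.33,0.94
P_010,left,ground_truth,14.40,0.73
P_010,left,mlm,17.47,0.88
P_010,left,counts,19.42,0.98
P_001,right,ground_truth,16.80,0.59
P_001,right,mlm,19.60,0.69
P_001,right,counts,26.22,0.92
P_002,right,ground_truth,13.53,0.76
P_002,right,mlm,15.67,0.88
P_002,right,counts,16.70,0.94
P_003,right,ground_truth,23.27,0.84
P_003,right,mlm,23.93,0.86
P_003,right,counts,27.13,0.98
P_004,right,ground_truth,17.33,0.58
P_004,right,mlm,20.60,0.69
P_004,right,counts,27.98,0.94
P_005,right,ground_truth,12.73,0.72
P_005,right,mlm,15.47,0.88
P_005,right,counts,16.82,0.95
P_006,right,ground_truth,13.80,0.65
P_006,right,mlm,15.27,0.72
P_006,right,counts,20.50,0.97
P_007,right,ground_truth,11.27,0.71
P_007,right,mlm,12.93,0.82
P_007,right,counts,14.87,0.94
P_008,right,ground_truth,17.07,0.80
P_008,right,mlm,19.60,0.92
P_008,right,counts,20.35,0.95
P_009,right,ground_truth,15.33,0.71
P_009,right,mlm,17.27,0.79
P_009,right,counts,20.32,0.94
P_010,right,ground_truth,14.53,0.73
P_010,right,mlm,17.47,0.88
P_010,right,counts,19.57,0.99
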