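# Published per-participant classifier metrics (accuracy, recall, specificity, f1)
# per arm side for the ten-participant home-monitoring validation cohort (fixture v1).
# Values as printed, rounded to 2 decimals; the printed column averages are
# left: acc 0.83, recall 0.96, spec 0.82, f1 0.35 / right: acc 0.85, recall 0.77, spec 0.85, f1 0.47.
participant,side,accuracy,recall,specificity,f1
P_001,left,0.82,0.96,0.80,0.47
P_002,left,0.82,1.00,0.80,0.53
P_003,left,0.90,0.89,0.90,0.30
P_004,left,0.83,0.94,0.83,0.32
P_005,left,0.77,1.00,0.76,0.23
P_006,left,0.80,0.85,0.80,0.31
P_007,left,0.85,1.00,0.84,0.36
P_008,left,0.81,1.00,0.80,0.33
P_009,left,0.88,0.95,0.88,0.55
P_010,left,0.83,1.00,0.82,0.12
P_001,right,0.82,0.75,0.83,0.45
P_002,right,0.87,0.94,0.86,0.63
P_003,right,0.89,0.30,0.93,0.25
P_004,right,0.83,0.87,0.82,0.57
P_005,right,0.78,0.74,0.79,0.45
P_006,right,0.88,0.82,0.89,0.55
P_007,right,0.88,1.00,0.87,0.63
P_008,right,0.83,0.72,0.84,0.44
P_009,right,0.86,0.75,0.86,0.47
P_010,right,0.81,0.75,0.82,0.32
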