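# Published detection benchmark for scattered-shrub instance segmentation:
# per-experiment true/false positive/negative counts and the reported
# precision/recall/F1, across three image resolutions (UAV 0.03, Airborne 0.1,
# GE 0.5 m/pixel). 7 rows are known to be arithmetically inconsistent with
# their own printed counts under any rounding rule (flagged inconsistent=1).
experiment,image,tp,fp,fn,precision,recall,f1,inconsistent
1.1.A,UAV,55,5,10,0.92,0.85,0.88,0
1.1.A,Airborne,56,4,9,0.93,0.86,0.90,0
1.1.A,GE,50,1,15,0.98,0.77,0.86,0
1.1.B,UAV,59,6,6,0.91,0.91,0.91,0
1.1.B,Airborne,60,7,5,0.90,0.92,0.91,0
1.1.B,GE,55,2,10,0.96,0.85,0.90,0
1.1.C,UAV,55,1,10,0.98,0.85,0.91,0
1.1.C,Airborne,52,3,13,0.94,0.80,0.87,1
1.1.C,GE,53,0,12,1.00,0.81,0.89,1
1.2.A,UAV,53,1,12,0.98,0.82,0.89,0
1.2.A,Airborne,54,1,11,0.98,0.83,0.90,0
1.2.A,GE,42,3,23,0.93,0.65,0.76,0
1.2.B,UAV,55,1,10,0.98,0.85,0.91,0
1.2.B,Airborne,50,2,15,0.96,0.77,0.85,0
1.2.B,GE,50,2,15,0.96,0.77,0.85,0
1.2.C,UAV,56,3,8,0.95,0.87,0.91,1
1.2.C,Airborne,52,3,13,0.94,0.80,0.87,1
1.2.C,GE,54,1,12,0.98,0.81,0.89,1
2.1.A,UAV,41,0,24,1.00,0.63,0.77,0
2.1.A,Airborne,38,0,27,1.00,0.58,0.74,0
2.1.A,GE,34,1,31,0.97,0.52,0.68,0
2.1.B,UAV,47,0,18,1.00,0.72,0.84,0
2.1.B,Airborne,55,3,10,0.95,0.85,0.89,0
2.1.B,GE,50,1,16,0.98,0.76,0.85,0
2.1.C,UAV,52,1,13,0.98,0.80,0.88,0
2.1.C,Airborne,58,3,7,0.95,0.88,0.91,1
2.1.C,GE,54,1,12,0.98,0.82,0.89,0
2.2.A,UAV,31,0,34,1.00,0.48,0.65,0
2.2.A,Airborne,48,1,17,0.98,0.74,0.84,0
2.2.A,GE,38,1,27,0.97,0.58,0.73,0
2.2.B,UAV,38,1,27,0.97,0.58,0.73,0
2.2.B,Airborne,46,1,19,0.98,0.71,0.82,0
2.2.B,GE,47,3,18,0.94,0.72,0.82,0
2.2.C,UAV,46,1,19,0.98,0.70,0.82,1
2.2.C,Airborne,51,2,14,0.96,0.78,0.86,0
2.2.C,GE,50,2,15,0.96,0.77,0.85,0
3.1.A,UAV,37,0,28,1.00,0.57,0.73,0
3.1.A,Airborne,43,0,22,1.00,0.66,0.80,0
3.1.A,GE,41,1,24,0.98,0.63,0.77,0
3.1.B,UAV,48,1,17,0.98,0.74,0.84,0
3.1.B,Airborne,51,1,14,0.98,0.78,0.87,0
3.1.B,GE,54,1,11,0.98,0.83,0.90,0
3.1.C,UAV,52,1,13,0.98,0.80,0.88,0
3.1.C,Airborne,52,1,13,0.98,0.80,0.88,0
3.1.C,GE,54,2,11,0.96,0.83,0.89,0
3.2.A,UAV,54,1,11,0.98,0.83,0.90,0
3.2.A,Airborne,56,4,9,0.93,0.86,0.90,0
3.2.A,GE,53,2,12,0.96,0.82,0.88,0
3.2.B,UAV,56,3,9,0.95,0.86,0.90,0
3.2.B,Airborne,54,5,11,0.92,0.83,0.87,0
3.2.B,GE,53,3,12,0.95,0.82,0.88,0
3.2.C,UAV,54,3,11,0.95,0.83,0.89,0
3.2.C,Airborne,52,3,13,0.95,0.80,0.87,0
3.2.C,GE,52,3,13,0.95,0.80,0.87,0
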