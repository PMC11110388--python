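tool_number,tool_name,n,tp,fp,tn,fn,sensitivity,sens_lcl,sens_ucl,specificity,spec_lcl,spec_ucl,lr_pos,lr_pos_lcl,lr_pos_ucl,lr_neg,lr_neg_lcl,lr_neg_ucl
1,LAS Step 1,2757,303,151,1647,656,0.32,0.29,0.35,0.92,0.90,0.93,3.76,3.15,4.50,0.75,0.64,0.88
2,LAS Steps 1/2,2757,540,266,1532,419,0.56,0.53,0.59,0.85,0.84,0.87,3.81,3.36,4.31,0.51,0.45,0.59
3,LAS Steps 1/2/3,2757,548,267,1531,411,0.57,0.54,0.60,0.85,0.84,0.87,3.85,3.40,4.35,0.50,0.44,0.57
4,LAS Steps 1/2/3/4,2757,836,1272,526,123,0.87,0.85,0.89,0.29,0.27,0.31,1.23,1.19,1.28,0.44,0.37,0.52
5,SWAS,2757,319,135,1663,640,0.33,0.30,0.36,0.92,0.91,0.94,4.43,3.68,5.33,0.72,0.61,0.85
6,WMAS Step 1,2757,333,164,1634,626,0.35,0.32,0.38,0.91,0.90,0.92,3.81,3.21,4.51,0.72,0.62,0.84
7,WMAS Steps 1/2,2757,443,224,1574,516,0.46,0.43,0.49,0.88,0.86,0.89,3.71,3.22,4.27,0.61,0.54,0.70
8,WMAS Steps 1/2/3,2757,509,261,1537,450,0.53,0.50,0.56,0.85,0.84,0.87,3.66,3.22,4.15,0.55,0.48,0.63
9,WMAS Steps 1/2/3/4,2757,827,1295,503,132,0.86,0.84,0.88,0.28,0.26,0.30,1.20,1.15,1.24,0.49,0.42,0.58
10,YAS Step 1,2757,308,168,1630,651,0.32,0.29,0.35,0.91,0.89,0.92,3.44,2.90,4.08,0.75,0.64,0.87
11,YAS Steps 1/2,2757,501,283,1515,458,0.52,0.49,0.55,0.84,0.83,0.86,3.32,2.94,3.75,0.57,0.50,0.64
12,YAS Steps 1/2/3,2757,510,284,1514,449,0.53,0.50,0.56,0.84,0.83,0.86,3.37,2.98,3.80,0.56,0.49,0.63
13,YAS Steps 1/2/3/4,2757,809,1289,509,150,0.84,0.82,0.87,0.28,0.26,0.30,1.18,1.13,1.22,0.55,0.48,0.64
14,LAS triage decisions,622,118,50,399,55,0.68,0.61,0.75,0.89,0.86,0.92,6.13,4.63,8.11,0.36,0.25,0.50
15,SWAS triage decisions,687,66,9,422,190,0.26,0.20,0.31,0.98,0.97,0.99,12.35,6.26,24.35,0.76,0.40,1.45
16,WMAS triage decisions,801,154,11,471,165,0.48,0.43,0.54,0.98,0.96,0.99,21.15,11.67,38.36,0.53,0.29,0.96
17,YAS triage decisions,647,108,25,411,103,0.51,0.44,0.58,0.94,0.92,0.96,8.93,5.97,13.35,0.52,0.35,0.78
18,Overall triage decisions,2757,446,95,1703,513,0.47,0.43,0.50,0.95,0.94,0.96,8.80,7.16,10.83,0.56,0.46,0.69
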