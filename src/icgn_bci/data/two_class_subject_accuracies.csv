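subject,LSTM,ICGN,BiLSTM
1,77.75,91.21,85.31
2,84.13,91.82,88.69
3,83.03,90.63,89.46
4,80.52,86.04,86.59
5,88.95,92.00,90.45
6,85.90,91.89,91.43
7,86.15,93.27,88.71
8,83.72,90.91,88.67
9,87.58,92.00,89.97
10,90.43,91.70,91.51
11,84.39,90.28,89.56
12,86.01,90.89,88.57
13,87.77,90.63,90.54
14,82.25,93.97,87.50
15,76.27,91.15,86.26
16,90.43,91.42,91.27
17,87.59,92.33,86.72
18,80.58,89.73,85.92
19,87.64,90.89,88.36
20,86.68,92.81,91.34
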