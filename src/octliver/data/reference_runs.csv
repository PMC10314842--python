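run_id,sensitivity,specificity,ppv,npv,accuracy,f1
A1,0.91,0.95,0.94,0.92,0.93,0.92
A2,0.96,0.92,0.91,0.96,0.94,0.94
A3,0.95,0.91,0.91,0.96,0.93,0.93
A4,0.97,0.94,0.93,0.97,0.95,0.95
A5,0.90,0.96,0.95,0.92,0.93,0.92
B1,0.86,0.93,0.92,0.89,0.90,0.89
B2,0.98,0.95,0.94,0.99,0.96,0.96
B3,0.96,0.94,0.94,0.97,0.95,0.95
B4,0.97,0.95,0.94,0.97,0.96,0.95
B5,0.86,0.92,0.90,0.88,0.89,0.88
C1,0.89,0.78,0.78,0.89,0.83,0.83
C2,0.92,0.93,0.92,0.93,0.93,0.92
C3,0.90,0.95,0.94,0.91,0.93,0.92
C4,0.98,0.95,0.95,0.98,0.96,0.96
C5,0.96,0.94,0.93,0.96,0.95,0.94
D1,0.90,0.89,0.88,0.91,0.89,0.89
D2,0.97,0.92,0.91,0.97,0.94,0.94
D3,0.99,0.95,0.94,1.00,0.97,0.97
D4,0.91,0.96,0.95,0.93,0.94,0.93
D5,0.96,0.94,0.93,0.97,0.95,0.95
E1,0.92,0.96,0.95,0.93,0.94,0.94
E2,0.98,0.90,0.90,0.98,0.94,0.93
E3,0.88,0.93,0.92,0.90,0.91,0.90
E4,0.95,0.94,0.93,0.96,0.95,0.94
E5,0.96,0.93,0.92,0.97,0.94,0.94
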