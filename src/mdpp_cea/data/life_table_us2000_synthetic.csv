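age,sex,q_annual
45,F,0.002283
46,F,0.002486
47,F,0.002706
48,F,0.002946
49,F,0.003206
50,F,0.003490
51,F,0.003799
52,F,0.004136
53,F,0.004502
54,F,0.004900
55,F,0.005334
56,F,0.005806
57,F,0.006319
58,F,0.006878
59,F,0.007486
60,F,0.008147
61,F,0.008867
62,F,0.009650
63,F,0.010501
64,F,0.011428
65,F,0.012435
66,F,0.013531
67,F,0.014722
68,F,0.016018
69,F,0.017426
70,F,0.018958
45,M,0.004002
46,M,0.004357
47,M,0.004742
48,M,0.005162
49,M,0.005619
50,M,0.006115
51,M,0.006656
52,M,0.007245
53,M,0.007885
54,M,0.008581
55,M,0.009339
56,M,0.010163
57,M,0.011060
58,M,0.012035
59,M,0.013096
60,M,0.014249
61,M,0.015504
62,M,0.016868
63,M,0.018350
64,M,0.019962
65,M,0.021713
66,M,0.023617
67,M,0.025685
68,M,0.027931
69,M,0.030371
70,M,0.033021
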