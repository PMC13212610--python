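subject,measured_gradient_mmhg,cfdm_flow_ml_s,cfdm_gradient_mmhg,cfdi_flow_ml_s,cfdi_gradient_mmhg
1,5.9,1.26,5.3,2.90,4.6
2,28.5,1.26,31.6,1.08,24.5
3,8.0,1.26,3.4,2.64,12.3
4,25.1,1.26,12.4,1.81,23.9
5,3.0,1.26,3.1,2.08,7.1
6,10.3,1.26,6.1,1.64,9.3
7,10.0,1.26,1.4,2.08,5.5
8,2.9,1.26,5.9,0.92,4.1
9,14.7,1.26,7.9,1.60,11.7
10,16.8,1.26,12.2,1.60,18.9
11,7.2,1.26,2.4,3.26,8.7
12,6.2,1.26,15.3,1.08,11.9
13,37.3,1.26,23.0,2.18,36.9
14,10.7,1.26,1.8,3.78,12.4
15,5.9,1.26,0.5,4.2,5.0
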