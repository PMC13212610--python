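subject,resting_pd_pa,measured_ffr,simulated_ffr,hyperemic_flow_ml_s
1,0.93,0.69,0.73,6.9
2,0.62,0.41,0.33,1.4
5,0.97,0.79,0.75,4.4
6,0.91,0.67,0.70,3.3
7,0.89,0.68,0.81,4.7
8,0.97,0.97,0.91,1.2
10,0.78,0.51,0.57,2.1
12,0.94,0.63,0.67,2.1
15,0.92,0.72,0.73,11.5
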