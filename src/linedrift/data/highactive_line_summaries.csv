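trait_name,experiment,ha_mean,ha_sem,ha_n,c_mean,c_sem,c_n,h2,n_families
Home Cage Activity,1,0.92,0.10,14,0.44,0.06,14,0.33,12
Hits,1,28.2,0.44,14,23.7,1.37,14,0.4,12
Hits latency,1,1.53,0.12,14,2.24,0.22,14,0.18,12
FA (V1),1.1,16.5,1.39,7,9.59,1.50,7,0.17,12
FA (V2),1.2,28.3,0.38,7,24.8,1.40,7,0.17,11
FA latency (V1),1.1,3.43,0.14,7,4.16,0.12,7,0.06,12
FA latency (V2),1.2,1.39,0.09,7,1.91,0.26,7,0.06,11
Precue response,1,19.15,3.08,14,18.14,2.7,14,,
Cue side poke,1,142.7,17.2,14,156.6,33.9,14,,
Efficiency,1,18.60,2.5,14,18.40,2.26,14,,
Home Cage Activity,2,1.36,0.25,18,0.53,0.11,13,0.33,13
Y-maze arm entries,2,63.8,4.18,20,42.0,3.12,23,0.39,18
Rotarod latency (s),2,31.7,2.06,20,43.3,3.90,23,0.44,18
Hits,2,19.8,2.10,8,12.6,3.47,4,0.4,13
AMPH on Hits,2,0.43,1.28,10,6.42,1.77,9,0.21,13
Hits latency,2,1.56,0.1,8,1.82,0.19,4,,
AMPH on Hits latency,2,-0.14,0.09,10,-0.23,0.10,9,,
FA,2,9.45,1.59,8,3.20,0.78,4,0.17,13
AMPH on FA,2,-1.35,1.1,10,3.87,0.51,9,0.21,13
FA latency,2,2.11,0.07,8,2.36,0.03,4,,
AMPH on FA latency,2,0.03,0.05,10,-0.13,0.03,9,0.21,13
Precue response,2,19.96,4.8,8,4.3,1.54,4,,
Cue side poke,2,83.28,23.2,8,23.1,6.49,4,,
Efficiency,2,25.53,4.5,8,73.6,16.4,4,,
Home Cage Activity,3,0.72,0.11,9,0.31,0.04,12,0.33,11
Hits,3,20.5,0.82,5,13.0,0.50,4,0.4,11
AMPH on Hits,3,-3.10,1.2,7,3.42,1.59,5,0.21,11
Hits latency,3,2.94,0.12,5,3.72,0.08,4,0.18,11
AMPH on Hits latency,3,0.36,0.15,7,-0.49,0.3,5,0.21,11
FA,3,8.22,0.50,5,5.30,0.64,4,0.17,11
AMPH on FA,3,-2.08,0.8,7,-0.46,0.5,5,,
FA latency,3,4.25,0.05,5,4.53,0.08,4,0.06,11
AMPH on FA latency,3,0.22,0.08,7,0.07,0.04,5,,
Precue response,3,13.3,0.89,5,10.2,1.2,4,,
Cue side poke,3,60.9,9.27,5,51.1,15.8,4,,
Efficiency,3,20.9,1.45,5,24.6,2.7,4,,
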