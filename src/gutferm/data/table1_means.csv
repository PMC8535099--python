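taxon,BL:0,FOS:6,FOS:18,FOS:24,FLS:6,FLS:18,FLS:24,BC:6,BC:18,BC:24
Eubacteria,8.27±0.22,8.61±0.12,8.69±0.16,8.96±0.17,8.29±0.11,8.41±0.11,8.82±0.12,8.36±0.10,8.18±0.08,8.34±0.07
Firmicutes,7.37±0.20,7.45±0.07,7.84±0.08,8.43±0.07,7.54±0.13,7.56±0.14,8.68±0.09,7.38±0.02,7.35±0.22,7.16±0.15
Bacteroidetes,6.41±0.18,6.61±0.15,7.25±0.13,8.26±0.07,5.91±0.16,6.14±0.10,7.75±0.18,6.22±0.24,5.16±0.03,4.77±0.11
Lactobacillales,6.67±0.13,7.27±0.17,7.69±0.12,8.23±0.12,6.98±0.23,7.14±0.11,8.17±0.14,6.55±0.07,6.71±0.11,6.63±0.08
Bifidobacteriaceae,7.21±0.08,7.71±0.08,7.88±0.04,7.96±0.04,6.69±0.20,6.69±0.12,8.11±0.17,6.56±0.21,6.18±0.04,5.20±0.12
Enterobacteriaceae,6.77±0.19,6.99±0.21,7.09±0.22,6.31±0.24,7.04±0.07,6.98±0.08,6.55±0.11,7.10±0.28,8.10±0.28,8.33±0.34
Clostridium gI,2.13±0.29,3.48±0.43,3.49±0.41,2.35±0.13,4.28±0.27,4.95±0.29,4.33±0.23,4.20±0.30,6.19±0.30,6.16±0.51
Clostridium gIV,7.43±0.11,7.35±0.18,7.33±0.19,7.20±0.16,6.66±0.23,6.34±0.23,6.57±0.04,7.53±0.19,7.38±0.28,7.37±0.08
E. coli,3.96±0.06,4.24±0.05,4.05±0.06,3.81±0.03,4.30±0.15,4.11±0.06,4.03±0.05,5.08±0.25,6.44±0.13,6.79±0.09
F. prausnitzii,7.53±0.12,7.66±0.07,8.05±0.12,8.57±0.24,7.57±0.25,7.13±0.04,8.12±0.15,7.07±0.08,6.88±0.05,6.49±0.11
A. muciniphila,4.19±0.13,4.87±0.10,4.55±0.18,4.58±0.16,4.15±0.07,4.34±0.08,4.95±0.05,4.53±0.07,3.40±0.03,3.20±0.04
F/B,1.15±0.20,1.13±0.11,1.08±0.10,1.02±0.07,1.28±0.14,1.23±0.12,1.12±0.14,1.19±0.13,1.42±0.13,1.50±0.12
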