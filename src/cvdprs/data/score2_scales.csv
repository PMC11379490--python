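# SCORE2 regional recalibration scales: risk_cal = 1-exp(-exp(scale1+scale2*ln(-ln(1-risk)))).
region,sex,scale1,scale2
low,M,-0.5699,0.7476
low,F,-0.7380,0.7019
moderate,M,-0.1565,0.8009
moderate,F,-0.3143,0.7701
high,M,0.3207,0.9360
high,F,0.5710,0.9369
very_high,M,0.5836,0.8294
very_high,F,0.9412,0.8329
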