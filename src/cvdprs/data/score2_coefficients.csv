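# SCORE2 sex-specific Cox coefficients (ESC 2021 algorithm, supplementary tables).
# Inputs are centred/scaled: cage=(age-60)/5, csbp=(sbp-120)/20, ctchol=(tchol-6)/1 mmol/L,
# chdl=(hdl-1.3)/0.5 mmol/L, smoking current=1. baseline_survival is the 10-year S0.
sex,term,value
M,age,0.3742
M,smoking,0.6012
M,sbp,0.2777
M,tchol,0.1458
M,hdl,-0.2698
M,smoking_age,-0.0755
M,sbp_age,-0.0255
M,tchol_age,-0.0281
M,hdl_age,0.0426
M,baseline_survival,0.9605
F,age,0.4648
F,smoking,0.7744
F,sbp,0.3131
F,tchol,0.1002
F,hdl,-0.2606
F,smoking_age,-0.1088
F,sbp_age,-0.0277
F,tchol_age,-0.0226
F,hdl_age,0.0613
F,baseline_survival,0.9776
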