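# ASCVD Pooled Cohort Equations, race/sex-specific proportional-hazards coefficients
# (2013 ACC/AHA risk assessment guideline, appendix tables). Linear predictor terms on
# ln-transformed inputs in equation units (age years, cholesterol mg/dL, SBP mmHg).
# mean_lp is the published group mean of the linear predictor; baseline_survival is S0(10y).
sex,race,term,value
F,white,ln_age,-29.799
F,white,ln_age_sq,4.884
F,white,ln_tc,13.540
F,white,ln_age_ln_tc,-3.114
F,white,ln_hdl,-13.578
F,white,ln_age_ln_hdl,3.149
F,white,ln_sbp_treated,2.019
F,white,ln_age_ln_sbp_treated,0.0
F,white,ln_sbp_untreated,1.957
F,white,ln_age_ln_sbp_untreated,0.0
F,white,smoker,7.574
F,white,ln_age_smoker,-1.665
F,white,diabetes,0.661
F,white,mean_lp,-29.18
F,white,baseline_survival,0.9665
F,black,ln_age,17.114
F,black,ln_age_sq,0.0
F,black,ln_tc,0.940
F,black,ln_age_ln_tc,0.0
F,black,ln_hdl,-18.920
F,black,ln_age_ln_hdl,4.475
F,black,ln_sbp_treated,29.291
F,black,ln_age_ln_sbp_treated,-6.432
F,black,ln_sbp_untreated,27.820
F,black,ln_age_ln_sbp_untreated,-6.087
F,black,smoker,0.691
F,black,ln_age_smoker,0.0
F,black,diabetes,0.874
F,black,mean_lp,86.61
F,black,baseline_survival,0.9533
M,white,ln_age,12.344
M,white,ln_age_sq,0.0
M,white,ln_tc,11.853
M,white,ln_age_ln_tc,-2.664
M,white,ln_hdl,-7.990
M,white,ln_age_ln_hdl,1.769
M,white,ln_sbp_treated,1.797
M,white,ln_age_ln_sbp_treated,0.0
M,white,ln_sbp_untreated,1.764
M,white,ln_age_ln_sbp_untreated,0.0
M,white,smoker,7.837
M,white,ln_age_smoker,-1.795
M,white,diabetes,0.658
M,white,mean_lp,61.18
M,white,baseline_survival,0.9144
M,black,ln_age,2.469
M,black,ln_age_sq,0.0
M,black,ln_tc,0.302
M,black,ln_age_ln_tc,0.0
M,black,ln_hdl,-0.307
M,black,ln_age_ln_hdl,0.0
M,black,ln_sbp_treated,1.916
M,black,ln_age_ln_sbp_treated,0.0
M,black,ln_sbp_untreated,1.809
M,black,ln_age_ln_sbp_untreated,0.0
M,black,smoker,0.549
M,black,ln_age_smoker,0.0
M,black,diabetes,0.645
M,black,mean_lp,19.54
M,black,baseline_survival,0.8954
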