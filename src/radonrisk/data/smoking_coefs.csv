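term,level,estimate,se,scale
intercept,,-0.43,0.04,logit
male,,0.41,0.01,logit
age,18-24,-0.86,0.02,logit
age,25-34,-0.34,0.02,logit
age,35-44,-0.28,0.01,logit
age,55-64,0.24,0.02,logit
age,65-74,0.33,0.02,logit
age,75+,-0.03,0.02,logit
poverty,below,0.37,0.02,logit
income_not_reported,,-0.24,0.01,logit
race,black,-0.50,0.04,logit
race,native,0.29,0.06,logit
race,asian,-1.38,0.05,logit
race,islander,-0.34,0.12,logit
race,other,0.20,0.05,logit
race_male,black,0.18,0.03,logit
race_male,native,-0.07,0.09,logit
race_male,asian,0.91,0.06,logit
race_male,islander,0.07,0.17,logit
race_male,other,0.03,0.07,logit
state_tax,,0.08,0.03,logit
prev_state_prevalence,,0.03,0.01,logit
indoor_restrictions,,0.01,0.03,logit
cbsa_poverty_above_median,,-0.02,0.03,logit
cbsa_nonmetropolitan,,0.04,0.04,logit
variance,state,0.005,0.003,logit2
variance,state_black_slope,0.035,0.012,logit2
covariance,state_black_slope,-0.008,0.004,logit2
variance,cbsa,0.040,0.005,logit2
variance,household,0.521,0.012,logit2
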