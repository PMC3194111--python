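term,level,outcome,estimate,se,scale
intercept,,attached,1.14,0.03,logit
intercept,,crawl_space,-0.51,0.04,logit
intercept,,slab,-0.30,0.04,logit
intercept,,other_detached,-2.80,0.10,logit
poverty,below,attached,4.40,,or
poverty,below,crawl_space,1.74,,or
poverty,below,slab,1.40,,or
poverty,below,other_detached,2.36,,or
sex,male,attached,0.97,,or
sex,male,crawl_space,1.01,,or
sex,male,slab,1.00,,or
sex,male,other_detached,1.04,,or
race,black,attached,2.75,,or
race,black,crawl_space,1.46,,or
race,black,slab,1.56,,or
race,black,other_detached,1.73,,or
race,asian,attached,2.34,,or
race,asian,crawl_space,0.84,,or
race,asian,slab,2.07,,or
race,asian,other_detached,2.10,,or
race,other,attached,1.76,,or
race,other,crawl_space,1.22,,or
race,other,slab,1.50,,or
race,other,other_detached,2.10,,or
race,native,attached,1.91,,or
race,native,crawl_space,1.42,,or
race,native,slab,1.74,,or
race,native,other_detached,1.83,,or
region,Northeast,attached,0.44,,or
region,Northeast,crawl_space,0.04,,or
region,Northeast,slab,0.03,,or
region,Northeast,other_detached,0.09,,or
region,Midwest,attached,0.21,,or
region,Midwest,crawl_space,0.10,,or
region,Midwest,slab,0.04,,or
region,Midwest,other_detached,0.12,,or
region,West,attached,1.35,,or
region,West,crawl_space,1.04,,or
region,West,slab,1.09,,or
region,West,other_detached,0.64,,or
age,<18,attached,1.11,,or
age,<18,crawl_space,0.87,,or
age,<18,slab,1.07,,or
age,<18,other_detached,0.71,,or
age,18-24,attached,1.99,,or
age,18-24,crawl_space,1.01,,or
age,18-24,slab,1.09,,or
age,18-24,other_detached,0.91,,or
age,25-34,attached,2.68,,or
age,25-34,crawl_space,1.17,,or
age,25-34,slab,1.31,,or
age,25-34,other_detached,0.95,,or
age,35-44,attached,1.25,,or
age,35-44,crawl_space,0.94,,or
age,35-44,slab,1.08,,or
age,35-44,other_detached,0.64,,or
age,55-64,attached,1.08,,or
age,55-64,crawl_space,1.08,,or
age,55-64,slab,1.04,,or
age,55-64,other_detached,1.26,,or
age,65-74,attached,1.16,,or
age,65-74,crawl_space,1.19,,or
age,65-74,slab,1.10,,or
age,65-74,other_detached,1.33,,or
age,75+,attached,1.80,,or
age,75+,crawl_space,1.39,,or
age,75+,slab,1.10,,or
age,75+,other_detached,1.71,,or
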