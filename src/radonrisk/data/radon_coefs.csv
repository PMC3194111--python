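term,level,estimate,se,scale
intercept,,-0.02,0.09,log
region,Northeast,-0.35,0.12,log
region,South,0.026,0.14,log
region,West,-0.18,0.15,log
geo_potential,Medium,0.43,0.074,log
geo_potential,High,0.74,0.11,log
hdd,,0.00006,0.00002,log
diurnal_swing,,0.041,0.01,log
house_type,attached,-0.71,0.03,log
house_type,crawl_space,-0.059,0.04,log
house_type,slab,-0.4283,0.03144,log
house_type,other_detached,-0.5308,0.1243,log
variance,state,0.05,,log2
variance,psu,0.10,,log2
variance,ssu,0.10,,log2
variance,residual,1.00,,log2
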