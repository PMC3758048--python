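drug,source,n,gm_price_per_mg,ci_low,ci_high
hydromorphone,crowdsourced,75,3.29,2.74,3.96
buprenorphine,crowdsourced,34,2.13,1.69,2.69
oxymorphone,crowdsourced,38,1.57,1.27,1.95
methadone,crowdsourced,21,0.96,0.71,1.29
oxycodone,crowdsourced,454,0.97,0.90,1.04
hydrocodone,crowdsourced,228,0.81,0.74,0.89
morphine,crowdsourced,83,0.52,0.40,0.68
tramadol,crowdsourced,21,0.05,0.03,0.07
hydromorphone,law_enforcement,54,4.47,3.57,5.59
buprenorphine,law_enforcement,81,2.35,1.97,2.80
oxymorphone,law_enforcement,43,1.64,1.29,2.10
methadone,law_enforcement,81,1.16,1.01,1.37
oxycodone,law_enforcement,181,0.86,0.78,0.93
hydrocodone,law_enforcement,179,0.90,0.84,0.97
morphine,law_enforcement,81,0.67,0.59,0.75
tramadol,law_enforcement,37,0.09,0.07,0.12
hydromorphone,marketplace,14,3.55,3.09,4.08
buprenorphine,marketplace,12,2.58,2.13,3.13
oxymorphone,marketplace,6,1.58,0.73,3.43
methadone,marketplace,3,0.93,0.65,1.34
oxycodone,marketplace,43,0.99,0.83,1.18
hydrocodone,marketplace,46,0.97,0.90,1.05
morphine,marketplace,16,0.42,0.37,0.48
tramadol,marketplace,7,0.02,0.01,0.03
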