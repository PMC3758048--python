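drug,potency_factor,citation
hydromorphone,4,"US VA/DoD Clinical Practice Guideline for Management of Opioid Therapy for Chronic Pain, 2012"
oxymorphone,3,"US VA/DoD Clinical Practice Guideline for Management of Opioid Therapy for Chronic Pain, 2012"
methadone,1.5,"US VA/DoD Clinical Practice Guideline for Management of Opioid Therapy for Chronic Pain, 2012"
oxycodone,2,"US VA/DoD Clinical Practice Guideline for Management of Opioid Therapy for Chronic Pain, 2012"
hydrocodone,1,"US VA/DoD Clinical Practice Guideline for Management of Opioid Therapy for Chronic Pain, 2012"
morphine,1,"US VA/DoD Clinical Practice Guideline for Management of Opioid Therapy for Chronic Pain, 2012"
tramadol,0.3,"US VA/DoD Clinical Practice Guideline for Management of Opioid Therapy for Chronic Pain, 2012"
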