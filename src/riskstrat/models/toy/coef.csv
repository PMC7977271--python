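kind,key1,key2,weight
cc,CC_DIABETES,,0.32
cc,CC_DIABETES_COMP,,0.55
cc,CC_NEOPLASM,,0.38
cc,CC_METASTATIC,,1.20
cc,CC_HEART,,0.35
cc,CC_CHF,,0.60
cc,CC_PSYCH,,0.30
cc,CC_LUNG,,0.35
cc,CC_RENAL,,0.40
demo,F,0-35,0.12
demo,F,35-45,0.17
demo,F,45-55,0.22
demo,F,55-65,0.28
demo,F,65-75,0.58
demo,F,75-85,0.68
demo,F,85-inf,0.80
demo,M,0-35,0.14
demo,M,35-45,0.19
demo,M,45-55,0.25
demo,M,55-65,0.31
demo,M,65-75,0.61
demo,M,75-85,0.71
demo,M,85-inf,0.83
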