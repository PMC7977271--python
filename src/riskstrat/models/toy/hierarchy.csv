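dominant_cc,suppressed_cc
CC_DIABETES_COMP,CC_DIABETES
CC_METASTATIC,CC_NEOPLASM
CC_CHF,CC_HEART
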