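code,cc
DM1,CC_DIABETES
DM2,CC_DIABETES
DM2C,CC_DIABETES_COMP
DMREN,CC_DIABETES_COMP
NEO_BR,CC_NEOPLASM
NEO_PR,CC_NEOPLASM
NEO_CO,CC_NEOPLASM
MET1,CC_METASTATIC
CAD,CC_HEART
AFIB,CC_HEART
CHF,CC_CHF
DEP,CC_PSYCH
ANX,CC_PSYCH
SCZ,CC_PSYCH
COPD,CC_LUNG
ASTHMA,CC_LUNG
CKD3,CC_RENAL
CKD4,CC_RENAL
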