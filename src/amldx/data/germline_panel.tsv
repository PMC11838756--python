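# gene	inheritance	disease_domain
CHEK2	AD	hematologic
ETV6	AD	hematologic
RUNX1	AD	hematologic
TP53	AD	hematologic
PALB2	AD	hematologic
UBE2T	AD	hematologic
DDX41	AD	hematologic
GATA2	AD	hematologic
CEBPA	AD	hematologic
ANKRD26	AD	hematologic
SAMD9	AD	hematologic
SAMD9L	AD	hematologic
SBDS	AR	hematologic
FANCA	AR	hematologic
FANCC	AR	hematologic
BLM	AR	hematologic
NBN	AR	hematologic
MUTYH	AR	non_hematologic
MITF	AD	non_hematologic
CDH1	AD	non_hematologic
APC	AD	non_hematologic
RET	AD	non_hematologic
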