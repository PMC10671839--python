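lipid_drug_resistance_literature	lipid-metabolism enzymes implicated in cancer drug resistance (review-derived; user-editable)	ACLY	ACACA	ACACB	FASN	CPT1A	CPT1B	CPT1C	CPT2	SCD
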