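terminology_id	code	icon_id	provenance
meshlike	M-thyroiditis-subacute	icon_mesh	manual
icdlike	E06.1	icon_icd	manual
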