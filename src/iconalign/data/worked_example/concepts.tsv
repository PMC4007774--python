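terminology_id	code	label	parents	cross_ids
meshlike	M-thyroiditis-subacute	Thyroiditis, subacute		C0040149
icdlike	E06.1	Subacute thyroiditis		C0040149
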