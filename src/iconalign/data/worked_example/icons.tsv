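icon_id	component_id	primitive_id
icon_mesh	central-color	current-condition
icon_mesh	shape	disease
icon_mesh	central-pictogram	endocrine-system
icon_icd	central-color	current-condition
icon_icd	shape	disease
icon_icd	central-pictogram	thyroid
icon_icd	top-right-pictogram	inflammation
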