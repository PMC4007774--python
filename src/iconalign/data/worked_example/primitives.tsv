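primitive_id	label	component_id	parent_id
current-condition	Current condition	central-color	ROOT
disease	Disease	shape	ROOT
anatomy	Anatomical structure	central-pictogram	ROOT
endocrine-system	Endocrine system	central-pictogram	anatomy
thyroid	Thyroid	central-pictogram	endocrine-system
process	Process annotation	top-right-pictogram	ROOT
inflammation	Inflammation	top-right-pictogram	process
topright-neutral	Neutral	top-right-color	ROOT
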