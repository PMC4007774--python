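component_id	name	required	multi_valued
central-color	Central color	1	0
shape	Shape	1	0
central-pictogram	Central pictogram	0	0
top-right-color	Top-right color	0	0
top-right-pictogram	Top-right pictogram	0	1
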