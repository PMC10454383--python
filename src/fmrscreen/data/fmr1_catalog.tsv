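locus_id	chromosome_type	repeat_unit	normal_max	gray_max	premutation_max
FMR1	chrX	CGG	40	54	200
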