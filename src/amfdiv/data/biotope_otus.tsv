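biotope	marker	amf_otus
subalpine_meadow	ITS1	171
forest	ITS1	117
river_valley	ITS1	296
subalpine_meadow	ITS2	131
forest	ITS2	60
river_valley	ITS2	221
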