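stp_id	biotope	altitude_m
STP1	subalpine_meadow	2437
STP3	subalpine_meadow	2401
STP4	subalpine_meadow	2186
STP7	forest	1900
STP8	forest	1890
STP9	forest	1507
STP11	river_valley	1342
STP12	river_valley	1026
STP13	river_valley	795
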