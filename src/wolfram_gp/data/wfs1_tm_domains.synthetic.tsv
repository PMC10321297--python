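# protein_id: WFS1_SYNTHETIC
# provenance: synthetic stand-in for the wolframin transmembrane annotation; nine TM helices of realistic span placed in the central membrane-spanning region. NOT a database snapshot - replace with a dated UniProt export before analyzing real patient data.
# coordinates: 1-based residue indices, closed intervals
start	end	label
313	333	TM1
338	358	TM2
402	422	TM3
427	447	TM4
466	486	TM5
494	514	TM6
521	541	TM7
591	611	TM8
631	651	TM9
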