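mirna_id	target_lncrna_id	precursor_of_same_mirna
miR162a	LTCONS_00029262	1
miR393b	LTCONS_00051533	1
miR396c	LTCONS_00034708	1
miR396c	LTCONS_00034707	1
miR172d	LTCONS_00034806	1
miR172d	LTCONS_00034805	1
miR1850	LTCONS_00057871	1
miR1850	LTCONS_00041446	0
miR444b	LTCONS_00033178	1
miR444b	LTCONS_00033177	1
miR444b	LTCONS_00034231	0
miR444d	LTCONS_00034231	1
miR444d	LTCONS_00033177	0
miR444d	LTCONS_00033178	0
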