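mirna_id	lncrna_id	alignment_length	alignment_ratio	location	de_lncrna
miR162a	LTCONS_00029262	171	1	Chr2	1
miR166f	LTCONS_00014145	107	0.972	Chr10	1
miR169a	LTCONS_00001063	173	1	Chr1	1
miR394	LTCONS_00029635	110	1	Chr2	1
miR396c	LTCONS_00034708	141	1	Chr2	1
miR396c	LTCONS_00034707	141	1	Chr2	1
miR319b	LTCONS_00000824	197	1	Chr1	0
miR166k	LTCONS_00035053	127	1	Chr2	0
miR166h	LTCONS_00035053	119	1	Chr2	0
miR393b	LTCONS_00051533	132	0.977	Chr4	1
miR172d	LTCONS_00034806	130	1	Chr2	1
miR172d	LTCONS_00034805	130	1	Chr2	1
miR1430	LTCONS_00024512	139	0.958	Chr12	1
miR444b	LTCONS_00033178	138	1	Chr2	1
miR444b	LTCONS_00033177	138	1	Chr2	0
miR444d	LTCONS_00034231	143	1	Chr2	1
miR1848	LTCONS_00027106	69	0.921	Chr2	1
miR1850	LTCONS_00057871	133	0.985	Chr5	1
miR1428b	LTCONS_00007959	124	1	Chr1	1
miR1428d	LTCONS_00007959	124	0.919	Chr1	1
miR1846e	LTCONS_00081175	69	0.957	Chr9	1
miR1846e	LTCONS_00057746	69	0.928	Chr5	0
miR396f	LTCONS_00034891	176	1	Chr2	1
miR5083	LTCONS_00009921	380	1	Chr1	1
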