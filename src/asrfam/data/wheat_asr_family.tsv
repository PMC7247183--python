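gene_id	transcript_id	locus	exon_count	orf_bp	aa_len	mw_kda	pi	gravy
TaASR1D	TraesCS3D01G517400.1	chr3D: 600607844-600608597	2	663	220	23.26	6.19	-0.986
TaASR1B	TraesCS3B01G578500.1	chr3B: 807930370-807931125	2	660	219	23.14	6.03	-0.955
TaASR1A	TraesCS3A01G509800.1	chr3A: 730177607-730178363	2	660	219	23.18	6.25	-0.977
TaASR2A	TraesCS3A01G509900.1	chr3A: 730207889-730208652	2	657	218	23.21	6.24	-0.929
TaASR2D	TraesCS3D01G517300.1	chr3D: 600594427-600595179	2	657	218	23.20	6.24	-0.917
TaASR2B	TraesCS3B01G578400.1	chr3B: 807881862-807882916	2	666	221	23.45	6.10	-0.950
TaASR3A1	TraesCS3A01G510100.1	chr3A: 730279210-730279978	2	660	219	23.68	6.16	-1.074
TaASR3D	TraesCS3D01G517100.1	chr3D: 600563453-600564143	3	528	175	18.86	6.51	-1.106
TaASR3B	TraesCS3B01G578200.1	chr3B: 807812908-807813694	2	684	227	24.39	6.27	-1.087
TaASR3A2	TraesCS3A01G510200.1	chr3A: 730327845-730328798	2	693	230	24.91	7.79	-0.991
TaASR4D	TraesCS4D01G109500.1	chr4D: 88700513-88701275	2	414	137	15.30	6.06	-1.198
TaASR4B	TraesCS4B01G112000.1	chr4B: 125481409-125482171	2	417	138	15.46	6.14	-1.199
TaASR4A	TraesCS4A01G208400.1	chr4A: 501468566-501469147	3	405	134	15.00	6.11	-1.043
TaASR5A	TraesCS2A01G301500.1	chr2A: 516531874-516532791	2	795	264	28.83	5.19	-1.755
TaASR5B	TraesCS2B01G317600.1	chr2B: 453077970-453078937	2	840	279	30.34	4.97	-1.760
TaASR5D	TraesCS2D01G300100.1	chr2D: 382195603-382196510	2	789	262	28.65	5.20	-1.735
TaASR6D	TraesCS3D01G517700.1	chr3D: 600624824-600625221	2	285	94	10.37	9.74	-1.233
TaASR6A	TraesCS3A01G509700.1	chr3A: 730152160-730152564	2	285	94	10.40	9.82	-1.234
TaASR6B	TraesCS3B01G858500LC.1	chr3B: 807959304-807959643	2	231	76	8.65	9.65	-1.261
TaASR7D1	TraesCS3D01G517500.1	chr3D: 600617363-600617756	2	285	94	10.44	9.70	-1.219
TaASR7D2	TraesCS3D01G517600.1	chr3D: 600621726-600622110	2	276	91	10.10	9.87	-1.209
TaASR8B	TraesCS3B01G578800.1	chr3B: 808019716-808020116	2	294	97	10.84	9.99	-1.332
TaASR8D	TraesCS3D01G518000.1	chr3D: 600655220-600655626	2	294	97	10.81	10.04	-1.366
TaASR9A	TraesCS3A01G509400.1	chr3A: 730085763-730086163	2	294	97	10.76	9.99	-1.331
TaASR9B	TraesCS3B01G456200.1	chr3B: 697683251-697683662	2	303	100	11.04	9.99	-1.349
TaASR9D	TraesCS3D01G518100.1	chr3D: 600665541-600665933	2	303	100	11.16	10.14	-1.325
TaASR10A1	TraesCS3A01G692700LC.1	chr3A: 730031423-730032153	2	333	110	12.34	9.89	-1.286
TaASR10A2	TraesCS3A01G510700.1	chr3A: 730463302-730463736	2	333	110	12.34	9.89	-1.286
TaASR10U	TraesCSU01G240200.1	chrUn: 358203209-358203643	2	333	110	12.34	9.89	-1.286
TaASR10A3	TraesCS3A01G693700LC.1	chr3A: 730442877-730443311	2	333	110	12.34	9.89	-1.286
TaASR10A4	TraesCS3A01G693800LC.1	chr3A: 730591083-730591517	2	333	110	12.34	9.89	-1.286
TaASR10A5	TraesCS3A01G509200.1	chr3A: 730011752-730012186	2	333	110	12.34	9.89	-1.286
TaASR10A6	TraesCS3A01G509500.1	chr3A: 730092027-730092461	2	333	110	12.34	9.89	-1.286
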