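variant_id	gene_id	consequence	cdna_pos	protein_change	African	American	EastAsian	European	SouthAsian	polyphen	sift
rs358231	GBA3	stop_gained	1368	p.Y456X	0.029	0.108	0.2	0.153	0.076		
rs17612341	GBA3	missense	639	p.R213P	0.001	0.007	0.029	0.011	0.001	0.92	0.05
rs182102815	GBA3	missense	546	p.G182S	0.004				0.003	0.88	0.10
rs187070546	GBA3	missense	318	p.D106N	0.001	0.006	0.039		0.001	0.95	0.02
rs533876334	GBA3	missense	45	p.A15P	0.001					0.81	0.12
rs544339352	GBA3	missense	159	p.C53S	0.001					0.90	0.04
rs187359066	GBA3	missense	246	p.R82C	0.001					0.97	0.01
rs529839966	GBA3	missense	264	p.T88R	0.001					0.84	0.15
rs571805473	GBA3	missense	795	p.P265S	0.001					0.79	0.21
rs538886341	GBA3	missense	843	p.Y281C	0.001					0.93	0.03
rs200660617	GBA3	missense	918	p.V306A	0.001					0.72	0.26
rs371662599	GBA3	stop_gained	1041	p.Y347X	0.001						
rs200623163	GBA3	missense	1167	p.R389C	0.001					0.98	0.01
rs560225618	GBA3	missense	1206	p.K402E	0.001					0.76	0.22
rs186578587	GBA3	missense	1257	p.L419V	0.001					0.71	0.28
rs371075149	GBA3	missense	1266	p.N422K	0.001					0.89	0.07
rs191769903	GBA3	missense	1299	p.F433L	0.001					0.83	0.11
rs370728701	GBA3	missense	1314	p.V438A	0.001					0.86	0.09
rs421016	GBA	missense	1449	p.L483P	0.002	0.001	0.012	0.002		0.99	0.00
rs76763715	GBA	missense	1227	p.N409S		0.001		0.002		0.91	0.03
rs149171124	GBA	stop_gained	1281	p.E427X	0.001						
rs146519305	GBA	missense	1602	p.R534C				0.01		0.94	0.02
rs369068553	GBA	missense	1497	p.V499M	0.001					0.87	0.06
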