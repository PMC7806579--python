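mz	intensity	compound	species	note
116.0706	280000	l-proline	[M+H]+	base peak; reported m/z
138.0525	70000	l-proline	[M+Na]+	replacement series n=1
154.0265	60000	l-proline	[M+K]+	reported m/z
160.0345	30000	l-proline	[M+2Na-H]+	replacement series n=2
176.0084	25000	l-proline	[M+Na+K-H]+	reported m/z
231.1339	50000	l-proline	[2M+H]+	reported m/z
253.1158	25000	l-proline	[2M+Na]+	dimer series
269.0898	15000	l-proline	[2M+K]+	dimer series
275.0978	10000	l-proline	[2M+2Na-H]+	dimer replacement form
346.1972	20000	l-proline	[3M+H]+	trimer series
368.1791	10000	l-proline	[3M+Na]+	trimer series
384.1460	8000	l-proline	[3M+Ca-H]+	read as [3M+K]+ at -7.2 mmu; Ca reading +1.8 mmu
406.1280	7000	l-proline	[3M+Na+Ca-2H]+	read as [3M+Na+K-2H]+... at -7.1 mmu; Ca reading +1.9 mmu
219.0739	60000	unknown-218	[M+H]+	4-peak cluster candidate
241.0558	20000	unknown-218	[M+Na]+	
257.0298	12000	unknown-218	[M+K]+	
437.1405	8000	unknown-218	[2M+H]+	
120.0655	30000	unknown-119	[M+H]+	pair via [M+Na]+
142.0475	8000	unknown-119	[M+Na]+	
166.0863	12000	unknown-183	[M+H-H2O]+	pair via water loss
184.0969	40000	unknown-183	[M+H]+	
140.0683	25000	unknown-139	[M+H]+	ambiguous +-NH3 pair
157.0948	15000	unknown-139	[M+NH4]+	
91.0542	16000	background	[M+H]+	singleton
104.1070	16000	background	[M+H]+	singleton
112.0505	16000	background	[M+H]+	singleton
133.0316	16000	background	[M+H]+	singleton
145.0495	16000	background	[M+H]+	singleton
158.9606	16000	background	[M+H]+	singleton
217.1052	16000	background	[M+H]+	singleton
243.0622	16000	background	[M+H]+	singleton
297.1440	16000	background	[M+H]+	singleton
318.3005	16000	background	[M+H]+	singleton
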