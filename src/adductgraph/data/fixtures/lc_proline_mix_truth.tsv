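mz	intensity	compound	species	note
116.0706	250000	l-proline	[M+H]+	base peak; reported m/z
133.0972	35000	l-proline	[M+NH4]+	5th cluster member
154.0265	80000	l-proline	[M+K]+	reported m/z
176.0100	15000	trigonelline	[M+K]+	reported m/z; absorbed as proline [M+Na+K-H]+ at +1.6 mmu
231.1339	40000	l-proline	[2M+H]+	reported m/z
176.0407	15000	creatine	[M+2Na-H]+	7th cluster member
114.0662	90000	creatinine	[M+H]+	reported m/z; misread as creatine [M+H-H2O]+
132.0768	150000	creatine	[M+H]+	reported m/z; cluster candidate
149.1033	10000	creatine	[M+NH4]+	cluster member
152.0221	30000	creatinine	[M+K]+	reported m/z; misread as creatine [M+K-H2O]+
154.0587	25000	creatine	[M+Na]+	cluster member
170.0326	50000	creatine	[M+K]+	reported m/z
173.0922	50000	homocitrulline	[M+H-NH3]+	reported m/z; ties 190.1195 on explained TIC, loses on connectivity
178.0476	30000	homocitrulline	[M+Na-H-NH3]+	intensity = I(229)+I(379) completes the explained-TIC tie
190.1195	60000	homocitrulline	[M+H]+	reported m/z; selected candidate (connectivity 4 vs 3)
212.1005	30000	homocitrulline	[M+Na]+	cluster member
229.1306	20000	creatinine+proline	[M+H]+	reported m/z; heterodimer read as homocitrulline [M+Na+NH3]+ at +2.6 mmu
379.2299	10000	homocitrulline	[2M+H]+	cluster member
104.1070	10000	background	[M+H]+	singleton putative
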