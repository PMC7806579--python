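BEGIN IONS
TITLE=LC mix 1.35 min (reconstructed)
RTINSECONDS=81.000
104.10700 10000.00
114.06620 90000.00
116.07060 250000.00
132.07680 150000.00
133.09720 35000.00
149.10330 10000.00
152.02210 30000.00
154.02650 80000.00
154.05870 25000.00
170.03260 50000.00
173.09220 50000.00
176.01000 15000.00
176.04070 15000.00
178.04760 30000.00
190.11950 60000.00
212.10050 30000.00
229.13060 20000.00
231.13390 40000.00
379.22990 10000.00
END IONS
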