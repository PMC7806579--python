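BEGIN IONS
TITLE=FIA l-proline (reconstructed)
91.05420 16000.00
104.10700 16000.00
112.05050 16000.00
116.07060 280000.00
120.06550 30000.00
133.03160 16000.00
138.05250 70000.00
140.06830 25000.00
142.04750 8000.00
145.04950 16000.00
154.02650 60000.00
157.09480 15000.00
158.96060 16000.00
160.03450 30000.00
166.08630 12000.00
176.00840 25000.00
184.09690 40000.00
217.10520 16000.00
219.07390 60000.00
231.13390 50000.00
241.05580 20000.00
243.06220 16000.00
253.11580 25000.00
257.02980 12000.00
269.08980 15000.00
275.09780 10000.00
297.14400 16000.00
318.30050 16000.00
346.19720 20000.00
368.17910 10000.00
384.14600 8000.00
406.12800 7000.00
437.14050 8000.00
END IONS
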