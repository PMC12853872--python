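bsa_m2,threshold_g
1.35,199
1.40,218
1.45,238
1.50,260
1.55,284
1.60,310
1.65,338
1.70,370
1.75,404
1.80,441
1.85,482
1.90,527
1.95,575
2.00,628
2.05,687
2.10,750
2.15,819
2.20,895
2.25,978
2.30,1068
2.35,1167
2.40,1275
2.45,1393
2.50,1522
2.55,1662
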