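# Polycyclic aromatic hydrocarbon (PAH) degradation genes of
# Pseudomonas aeruginosa PAO1, as KEGG-annotated locus tags.
PA0153
PA0154
PA0230
PA0231
PA0232
PA0247
PA0480
PA0817
PA0865
PA0880
PA1205
PA1210
PA1253
PA1966
PA2009
PA2024
PA2083
PA2085
PA2217
PA2418
PA2507
PA2508
PA2509
PA2512
PA2513
PA2514
PA2515
PA2516
PA2517
PA2518
PA2546
PA3240
PA3389
PA3629
PA3935
PA4091
PA4092
PA4121
PA4122
PA4123
PA4124
PA4125
PA4190
PA4486
PA4515
PA5427
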