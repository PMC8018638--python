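# Lifetimes (cycles) of 20 steel specimens fatigue-tested at stress
# amplitude 35.5; read in occurrence order (row-wise, left to right).
156
173
125
852
559
442
168
286
261
227
285
253
166
133
309
247
112
202
365
702
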