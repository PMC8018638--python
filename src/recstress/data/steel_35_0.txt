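# Lifetimes (cycles) of 20 steel specimens fatigue-tested at stress
# amplitude 35.0; read in occurrence order (row-wise, left to right).
230
169
178
271
129
568
115
280
305
326
1101
285
734
177
493
218
342
431
143
381
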