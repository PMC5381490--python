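tissue	cluster	member
heart	1	miR-302a
heart	1	miR-302b
heart	1	miR-302c
heart	1	miR-302d
heart	1	miR-367
heart	2	miR-1-2
heart	2	miR-133a-1
skeletal muscle	1	miR-133b
skeletal muscle	1	miR-206
skeletal muscle	2	miR-1-2
skeletal muscle	2	miR-133a-1
placenta	1	miR-377
placenta	1	miR-154
placenta	2	mir-498
placenta	2	mir-512-1
placenta	2	mir-512-2
placenta	2	miR-520e
placenta	2	miR-519e
placenta	2	miR-520f
placenta	3	mir-527
placenta	3	mir-521-1
placenta	3	mir-522
placenta	3	mir-519a-1
placenta	4	mir-526a-1
placenta	4	miR-523
placenta	4	miR-518f
placenta	4	miR-520b
placenta	4	miR-518b
placenta	4	miR-520c
placenta	4	miR-518c
placenta	4	miR-524
placenta	4	miR-517a
placenta	4	miR-519d
placenta	5	mir-526b
placenta	5	miR-519c
placenta	5	miR-520a
placenta	5	miR-519b
placenta	5	miR-525
placenta	5	miR-523
placenta	5	miR-518f
placenta	5	miR-520b
placenta	5	miR-518b
placenta	6	miR-503
placenta	6	mir-450a-1
placenta	6	mir-450a-2
placenta	7	mir-373
placenta	7	mir-371a
placenta	7	mir-372
placenta	8	mir-516b-1
placenta	8	mir-526a-2
placenta	8	miR-518e
placenta	8	miR-518a-1
placenta	8	miR-518a-2
placenta	8	miR-517c
placenta	8	miR-518d
placenta	8	miR-520h
placenta	9	mir-516b-2
placenta	9	miR-520d
placenta	9	miR-517b
placenta	9	miR-520g
testis	1	miR-34b
testis	1	miR-34c
testis	2	miR-506
testis	2	miR-507
testis	2	miR-508
testis	2	mir-513a-2
testis	3	miR-510
testis	3	mir-514a-1
testis	3	mir-514a-2
testis	4	mir-509-1
testis	4	mir-509-2
testis	4	mir-509-3
brain	1	miR-199a-2
brain	1	mir-214
brain	2	miR-99b
brain	2	miR-125a
thymus	1	miR-96
thymus	1	miR-182
pancreas	1	miR-216a
pancreas	1	miR-217
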