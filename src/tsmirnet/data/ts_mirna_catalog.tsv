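tissue	mirna
heart	miR-1
heart	miR-126
heart	miR-208
heart	miR-302a
heart	miR-302b
heart	miR-302c
heart	miR-302d
heart	miR-367
heart	miR-133a
heart	miR-133b
skeletal muscle	miR-1
skeletal muscle	miR-206
skeletal muscle	miR-134
skeletal muscle	miR-193a
skeletal muscle	miR-128a
skeletal muscle	miR-133a
skeletal muscle	miR-133b
skeletal muscle	miR-95
skeletal muscle	miR-208a
lung	miR-126
bone	miR-483
bone	miR-377
bone	miR-92a
kidney	miR-200a
kidney	miR-196a
kidney	miR-196b
kidney	miR-10a
kidney	miR-10b
kidney	miR-146a
kidney	miR-30c
kidney	miR-204
liver	miR-122
liver	miR-483
liver	miR-92a
liver	miR-192
placenta	miR-377
placenta	miR-498
placenta	miR-527
placenta	miR-526a
placenta	miR-526b
placenta	miR-184
placenta	miR-154
placenta	miR-381
placenta	miR-503
placenta	miR-373
placenta	miR-371
placenta	miR-372
placenta	miR-519a
placenta	miR-519b
placenta	miR-519c
placenta	miR-519d
placenta	miR-519e
placenta	miR-516b
placenta	miR-520a
placenta	miR-520b
placenta	miR-520c
placenta	miR-520d
placenta	miR-520e
placenta	miR-520f
placenta	miR-520g
placenta	miR-520h
placenta	miR-517a
placenta	miR-517b
placenta	miR-517c
placenta	miR-450
placenta	miR-518a
placenta	miR-518b
placenta	miR-518c
placenta	miR-518d
placenta	miR-518e
placenta	miR-518f
placenta	miR-522
placenta	miR-524
placenta	miR-521
placenta	miR-523
placenta	miR-525
placenta	miR-512
placenta	miR-136
testis	miR-134
testis	miR-187
testis	miR-34c
testis	miR-34b
testis	miR-507
testis	miR-510
testis	miR-513
testis	miR-506
testis	miR-508
testis	miR-509
testis	miR-514
testis	miR-449a
testis	miR-892b
testis	miR-202
brain	miR-199a
brain	miR-199b
brain	miR-214
brain	miR-153
brain	miR-137
brain	miR-7
brain	miR-143
brain	miR-99b
brain	miR-125a
brain	miR-125b
brain	miR-31
brain	miR-124
brain	miR-129
brain	miR-138
brain	miR-218
brain	miR-708
brain	miR-9
brain	miR-128a
brain	miR-128b
brain	miR-186
brain	miR-95
brain	miR-149
brain	miR-323
brain	miR-330
brain	miR-33a
brain	miR-346
brain	miR-93
brain	miR-212
spleen	miR-223
spleen	miR-146a
thymus	miR-96
thymus	miR-182
thymus	miR-205
pancreas	miR-216a
pancreas	miR-216b
pancreas	miR-217
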