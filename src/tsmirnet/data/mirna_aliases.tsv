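alias	mature
miR-208a	miR-208
miR-513a	miR-513
miR-514a	miR-514
miR-450a	miR-450
miR-371a	miR-371
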