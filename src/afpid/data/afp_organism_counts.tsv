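# Per-organism counts of the independent AFP sequence dataset (organism, n).
Algae	17
Bacteria	101
Fish	123
Insects	105
Plants	23
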