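code,term
M0101,oral NSAID (naproxen-like)
M0102,oral NSAID (ibuprofen-like)
M0103,oral NSAID (diclofenac-like)
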