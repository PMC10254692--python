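code,term
M0201,ulcer healing drug (PPI-like)
M0202,ulcer healing drug (H2 antagonist-like)
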