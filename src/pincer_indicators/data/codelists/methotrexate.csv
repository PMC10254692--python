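code,term
M0701,methotrexate oral
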