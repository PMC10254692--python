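code,term
M0301,aspirin (antiplatelet dose)
M0311,antiplatelet (clopidogrel-like)
M0312,antiplatelet (dipyridamole-like)
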