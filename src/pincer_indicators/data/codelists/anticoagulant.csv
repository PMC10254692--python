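code,term
M0401,warfarin-like anticoagulant
M0402,DOAC (apixaban-like)
M0403,DOAC (rivaroxaban-like)
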