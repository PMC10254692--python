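code,term
M0601,ACE inhibitor (ramipril-like)
M0602,ACE inhibitor (lisinopril-like)
M0611,loop diuretic (furosemide-like)
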