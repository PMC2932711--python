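# alternate symbol -> canonical symbol (tab-separated)
Sdccag33	Tshz1
Math5	Atoh7
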