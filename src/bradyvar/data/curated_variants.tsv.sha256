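857fcaef1f1d739397956bdc8add77e494484f1b7595f3ac7e8e3a1ebe9e2db2
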