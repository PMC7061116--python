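998733503062818b04cd0e23c0ffe7520f32cbe72576d51ad041d536974dfb4b
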