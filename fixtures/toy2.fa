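>toy2 8-base demonstration text
ACGTACGT
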