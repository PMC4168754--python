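# source	target
1000	ENSGTEST00000000
1002	ENSGTEST00000002
1003	ENSGTEST00000003
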