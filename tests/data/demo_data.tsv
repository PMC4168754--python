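id	logFC	p_value	adj_p_value
ENSGTEST00000000	-2.449378595	0.1024860202	0.4099440809
ENSGTEST00000001	-1.137659778	0.4481877081	0.8465947385
ENSGTEST00000002	0.6931125971	0.644027491	0.8465947385
ENSGTEST00000003	0.2901976449	0.8465947385	0.8465947385
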