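microhabitat,cover
OPEN,0.451
PISTACIA,0.27
EPHEDRA,0.175
OTHER,0.10399999999999987
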