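microhabitat,count
EPHEDRA,9
OPEN,106
OTHER,8
PISTACIA,17
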