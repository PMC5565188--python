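microhabitat,zone,transect
EPHEDRA,A,TA1
EPHEDRA,A,TA2
EPHEDRA,B,TB1
EPHEDRA,B,TB2
EPHEDRA,A,TA1
EPHEDRA,A,TA2
EPHEDRA,B,TB1
EPHEDRA,B,TB2
EPHEDRA,A,TA1
EPHEDRA,A,TA2
EPHEDRA,B,TB1
EPHEDRA,B,TB2
EPHEDRA,A,TA1
EPHEDRA,A,TA2
EPHEDRA,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OPEN,B,TB2
OPEN,A,TA1
OPEN,A,TA2
OPEN,B,TB1
OTHER,B,TB2
OTHER,A,TA1
OTHER,A,TA2
OTHER,B,TB1
OTHER,B,TB2
OTHER,A,TA1
OTHER,A,TA2
OTHER,B,TB1
OTHER,B,TB2
OTHER,A,TA1
PISTACIA,A,TA2
PISTACIA,B,TB1
PISTACIA,B,TB2
PISTACIA,A,TA1
PISTACIA,A,TA2
PISTACIA,B,TB1
PISTACIA,B,TB2
PISTACIA,A,TA1
PISTACIA,A,TA2
PISTACIA,B,TB1
PISTACIA,B,TB2
PISTACIA,A,TA1
PISTACIA,A,TA2
PISTACIA,B,TB1
PISTACIA,B,TB2
PISTACIA,A,TA1
PISTACIA,A,TA2
PISTACIA,B,TB1
PISTACIA,B,TB2
PISTACIA,A,TA1
PISTACIA,A,TA2
PISTACIA,B,TB1
PISTACIA,B,TB2
PISTACIA,A,TA1
PISTACIA,A,TA2
PISTACIA,B,TB1
PISTACIA,B,TB2
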