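human	mouse
IP-10	IP-10
MIG	MIG
IL-17	IL-17
IL-13	IL-13
IL-9	IL-9
Eotaxin	Eotaxin
VEGF	VEGF
IL-1a	IL-1a
GRO	KC
MIP-1b	MIP-1b
GM-CSF	GM-CSF
IFN-g	IFN-g
TNF-a	TNF-a
IL-2	IL-2
IL-12p70	IL-12p70
IL-15	IL-15
IL-1b	IL-1b
IFN-a2	IFN-a2
IL-6	IL-6
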