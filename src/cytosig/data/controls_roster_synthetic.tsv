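control	sex	excluded	exclusion_reason
C01	F	no
C02	F	no
C03	F	no
C04	F	no
C05	F	no
C06	F	no
C07	F	no
C08	F	no
C09	F	no
C10	F	no
C11	F	yes	surgical procedure within one week of sample collection
C12	M	no
C13	M	no
C14	M	no
C15	M	no
C16	M	no
C17	M	no
C18	M	no
C19	M	no
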