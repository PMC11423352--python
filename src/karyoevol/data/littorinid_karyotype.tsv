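chromosome	units
L1	ALG12,ALG4-1
L10	ALG7
L11	ALG8
L12	ALG9
L13	ALG10-1
L14	ALG14
L15	ALG10-2
L16	ALG15
L17	ALG17
L2	ALG16,ALG2-1,ALG5
L3	ALG11,ALG2-2
L4	ALG1
L5	ALG13-1
L6	ALG3
L7	ALG4-2
L8	ALG13-2
L9	ALG6
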