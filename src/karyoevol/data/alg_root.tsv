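chromosome	units
ALG1	ALG1
ALG10	ALG10
ALG11	ALG11
ALG12	ALG12
ALG13	ALG13
ALG14	ALG14
ALG15	ALG15
ALG16	ALG16
ALG17	ALG17
ALG2	ALG2
ALG3	ALG3
ALG4	ALG4
ALG5	ALG5
ALG6	ALG6
ALG7	ALG7
ALG8	ALG8
ALG9	ALG9
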