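chromosome	units
PY1	ALG10
PY10	ALG8
PY11	ALG11
PY12	ALG9
PY13	ALG2-2
PY14	ALG14
PY15	ALG15
PY16	ALG13-2
PY17	ALG4-2
PY18	ALG17
PY19	ALG2-1
PY2	ALG16,ALG5
PY3	ALG1
PY4	ALG3
PY5	ALG13-1
PY6	ALG6
PY7	ALG7
PY8	ALG12
PY9	ALG4-1
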