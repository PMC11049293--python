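marker
ARID1B
CCT8
DYRK1A
EZR
GART
INA
ITSN1
MRPL39
PCDH19
SNX9
SYNJ1
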