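prefix,drug_class
A10A,INSULIN
A10BB,SU
A10,OTHER_GLD
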