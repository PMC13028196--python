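atc_code,constituent_subgroups
A10BD02,A10BA;A10BB
A10BD03,A10BA;A10BG
A10BD04,A10BG;A10BB
A10BD05,A10BA;A10BG
A10BD06,A10BG;A10BB
A10BD07,A10BA;A10BH
A10BD08,A10BA;A10BH
A10BD10,A10BA;A10BH
A10BD11,A10BA;A10BH
A10BD13,A10BA;A10BH
A10BD15,A10BA;A10BK
A10BD16,A10BA;A10BK
A10BD19,A10BA;A10BX
A10BD20,A10BA;A10BK
A10BD21,A10BH;A10BK
A10BD23,A10BA;A10BK
A10BD25,A10BA;A10BH;A10BK
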