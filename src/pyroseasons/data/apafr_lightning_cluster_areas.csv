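cluster,area_ha
7,4668
other,2098
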