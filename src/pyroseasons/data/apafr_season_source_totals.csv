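source,season,n_fires,area_ha
lightning,wet,13,152
lightning,dry,3,521
lightning,fire,43,6093
military,wet,17,1154
military,dry,44,5853
military,fire,51,11115
prescribed,wet,118,15269
prescribed,dry,341,69681
prescribed,fire,205,41129
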