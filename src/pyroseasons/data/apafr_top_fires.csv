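source,rank,cluster,area_ha,date,temp,rh,solar,soil
lightning,1,7,1914,2006-05-27,25,77,0.26,4.9
lightning,2,7,1652,2000-06-24,25,82,0.25,3.7
lightning,3,7,549,1998-06-22,28,75,0.30,7.1
lightning,4,1,297,2007-06-12,26,73,0.26,27.5
lightning,5,3,269,2009-05-13,23,80,0.21,4.5
lightning,6,3,252,1997-03-02,23,77,0.20,12.0
lightning,7,7,247,2006-05-28,27,69,0.29,4.8
lightning,8,7,241,2000-06-06,28,71,0.30,3.2
lightning,9,1,226,2001-06-17,26,79,0.31,19.4
lightning,10,4,181,1997-05-07,22,70,0.28,18.6
military,1,6,2128,2006-05-04,24,61,0.32,7.2
military,2,4,1405,2001-03-07,13,48,0.29,3.5
military,3,7,1038,2000-06-15,27,72,0.29,3.4
military,4,6,748,2006-05-04,24,61,0.32,7.2
military,5,3,674,1999-02-12,21,86,0.12,19.7
military,6,1,651,1998-06-08,26,82,0.23,9.3
military,7,3,557,2007-12-15,23,86,0.10,9.5
military,8,5,547,2006-03-31,20,70,0.28,13.3
military,9,6,506,2006-05-04,24,61,0.32,7.2
military,10,3,452,1997-01-07,21,79,0.16,11.8
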