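value,uncertainty,year,kind,source
310,132,1969,measured,Vonach 1969
127,7,1970,measured,
418,15,1992,measured,
437.7,7.7,2004,measured,
448,27,2018,measured,
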