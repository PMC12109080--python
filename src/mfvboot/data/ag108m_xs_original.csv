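energy,value,uncertainty,year,kind,source
14.70,670,266,1969,measured,Vonach 1969
14.50,220,12,1991,measured,
14.50,263,20,1991,measured,
14.83,767,24,1991,evaluation,
14.60,232,8,1992,measured,
14.80,236,7,1992,measured,
14.70,628,42,1996,measured,
14.70,682,49,1996,measured,
14.50,697,60,1996,measured,
14.50,621,29,1996,evaluation,
14.80,648,31,1996,evaluation,
14.80,721,20,1996,evaluation,
14.50,695,40,1997,evaluation,
14.90,709,41,1997,evaluation,
14.50,643,30,1997,evaluation,
14.80,671,31,1997,evaluation,
14.70,651,44,1997,evaluation,
14.70,706,51,1997,evaluation,
14.50,677,82,1997,evaluation,
14.50,716,44,1997,evaluation,
14.77,784,25,1997,evaluation,
14.83,795,25,1997,evaluation,
14.60,790,27,1997,evaluation,
14.80,805,24,1997,evaluation,
14.80,800,55,2009,measured,
14.50,727,41,2016,measured,
14.80,747,42,2016,measured,
14.80,650,43,2024,measured,Song 2024
14.80,602,40,2024,measured,Song 2024
14.80,601,37,2024,measured,Song 2024
14.80,616,23,2024,measured,Song 2024
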