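energy,old_value,old_uncertainty,new_value,new_uncertainty,source
14.70,628,42,658,44,Song 2024
14.70,682,49,715,41,Song 2024
14.50,697,60,705,61,Song 2024
14.50,621,29,651,30,Song 2024
14.80,648,31,679,32,Song 2024
14.80,721,18,755,21,Song 2024
14.60,232,8,800,28,Song 2024
14.80,236,7,814,24,Song 2024
14.50,220,12,759,41,Song 2024
14.50,263,20,907,69,Song 2024
14.83,767,24,804,25,Song 2024
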