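EO,GWO,HGSO,BMO,MRFO,SSA,WOA,HHO
0.0033060,0.0032463,0.0032688,0.0032467,0.0032474,0.0032749,0.0033829,0.0032470
0.0033057,0.0032462,0.0032688,0.0032467,0.0032471,0.0032747,0.0033827,0.0032463
0.0033057,0.0032458,0.0032688,0.0032467,0.0032471,0.0032743,0.0033825,0.0032463
0.0033057,0.0032458,0.0032688,0.0032467,0.0032470,0.0032743,0.0033822,0.0032463
0.0033057,0.0032458,0.0032688,0.0032467,0.0032470,0.0032740,0.0033822,0.0031945
0.0033055,0.0032458,0.0032688,0.0032467,0.0032470,0.0032740,0.0033822,0.0031937
0.0033055,0.0032458,0.0032688,0.0032467,0.0032470,0.0032738,0.0033817,0.0031934
0.0033055,0.0032458,0.0032683,0.0032467,0.0032470,0.0032736,0.0033815,0.0031934
0.0033055,0.0032458,0.0032683,0.0032467,0.0032470,0.0032735,0.0033814,0.0031930
0.0033055,0.0032457,0.0032683,0.0032467,0.0032470,0.0032735,0.0033814,0.0031921
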