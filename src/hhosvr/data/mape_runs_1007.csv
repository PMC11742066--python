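EO,GWO,HGSO,BMO,MRFO,SSA,WOA,HHO
0.0033643,0.0033647,0.0033689,0.0033578,0.0033652,0.0033650,0.0035089,0.0033862
0.0033643,0.0033646,0.0033689,0.0033578,0.0033643,0.0033650,0.0035084,0.0033859
0.0033643,0.0033646,0.0033689,0.0033578,0.0033643,0.0033650,0.0035082,0.0033843
0.0033643,0.0033646,0.0033679,0.0033578,0.0033643,0.0033644,0.0035080,0.0033837
0.0033642,0.0033646,0.0033679,0.0033578,0.0033643,0.0033644,0.0035080,0.0033837
0.0033642,0.0033646,0.0033679,0.0033578,0.0033641,0.0033641,0.0035080,0.0033836
0.0033642,0.0033644,0.0033679,0.0033578,0.0033641,0.0033641,0.0035080,0.0032486
0.0033642,0.0033643,0.0033679,0.0033578,0.0033641,0.0033640,0.0035080,0.0032469
0.0033640,0.0033642,0.0033679,0.0033578,0.0033641,0.0033640,0.0035080,0.0032430
0.0033640,0.0033642,0.0033666,0.0033578,0.0033641,0.0033640,0.0035080,0.0032429
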