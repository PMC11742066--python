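EO,GWO,HGSO,BMO,MRFO,SSA,WOA,HHO
0.0052068,0.0052073,0.0052256,0.0052210,0.0052105,0.0052139,0.0052293,0.0051539
0.0052068,0.0052073,0.0052152,0.0052210,0.0052093,0.0052090,0.0052292,0.0051539
0.0052068,0.0052073,0.0052127,0.0052210,0.0052088,0.0052090,0.0052292,0.0051529
0.0052068,0.0052073,0.0052127,0.0052210,0.0052088,0.0052074,0.0052292,0.0051529
0.0052068,0.0052073,0.0052090,0.0052210,0.0052088,0.0052074,0.0052292,0.0051529
0.0052068,0.0052073,0.0052090,0.0052210,0.0052088,0.0052071,0.0052292,0.0051525
0.0052068,0.0052073,0.0052090,0.0052210,0.0052088,0.0052069,0.0052292,0.0051525
0.0052068,0.0052073,0.0052090,0.0052210,0.0052088,0.0052069,0.0052292,0.0051522
0.0052068,0.0052073,0.0052090,0.0052210,0.0052088,0.0052069,0.0052285,0.0051522
0.0052068,0.0052071,0.0052090,0.0052210,0.0052088,0.0052069,0.0052285,0.0051521
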