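EO,GWO,HGSO,BMO,MRFO,SSA,WOA,HHO
0.0123195,0.0123645,0.0123702,0.0123655,0.0122883,0.0123871,0.0123733,0.0124397
0.0123176,0.0123639,0.0123702,0.0123655,0.0122823,0.0123675,0.0123729,0.0124396
0.0123176,0.0123639,0.0123702,0.0123655,0.0122812,0.0123675,0.0123633,0.0124396
0.0123176,0.0123637,0.0123702,0.0123655,0.0122811,0.0123648,0.0123627,0.0124396
0.0123176,0.0123637,0.0123702,0.0123655,0.0122810,0.0123625,0.0123622,0.0124396
0.0123176,0.0123635,0.0123702,0.0123655,0.0122810,0.0123625,0.0123622,0.0124393
0.0123176,0.0123632,0.0123702,0.0123655,0.0122807,0.0123624,0.0123620,0.0124393
0.0123176,0.0123630,0.0123702,0.0123655,0.0122807,0.0123621,0.0123620,0.0124393
0.0123176,0.0123630,0.0123669,0.0123655,0.0122807,0.0123621,0.0123620,0.0124393
0.0123176,0.0123625,0.0123669,0.0123655,0.0122805,0.0123620,0.0123620,0.0124393
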