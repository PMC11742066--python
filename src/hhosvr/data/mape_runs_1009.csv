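EO,GWO,HGSO,BMO,MRFO,SSA,WOA,HHO
0.0049599,0.0049606,0.0049677,0.0048836,0.0049609,0.0049618,0.0054783,0.0049347
0.0049599,0.0049605,0.0049677,0.0048836,0.0049606,0.0049604,0.0054772,0.0049338
0.0049599,0.0049605,0.0049677,0.0048836,0.0049598,0.0049603,0.0054772,0.0049338
0.0049599,0.0049605,0.0049623,0.0048836,0.0049598,0.0049603,0.0054772,0.0049338
0.0049599,0.0049604,0.0049623,0.0048836,0.0049598,0.0049603,0.0054772,0.0049338
0.0049599,0.0049603,0.0049623,0.0048836,0.0049598,0.0049603,0.0054772,0.0049338
0.0049599,0.0049603,0.0049623,0.0048836,0.0049598,0.0049603,0.0054772,0.0049338
0.0049599,0.0049600,0.0049623,0.0048836,0.0049598,0.0049602,0.0054772,0.0049338
0.0049599,0.0049600,0.0049623,0.0048836,0.0049598,0.0049602,0.0054772,0.0049338
0.0049599,0.0049600,0.0049623,0.0048836,0.0049598,0.0049602,0.0054772,0.0049327
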