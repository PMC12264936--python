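id,name,r0,a1,b1,l_min
L1,P(3;5-diCF3C6H3)3,1.685,4.307,1.225,3.968
L2,P(C6F5)3,1.857,2.795,1.490,2.261
L3,P(CCl3)3,1.966,2.995,2.119,3.330
L4,P(CF3)3,2.032,2.460,1.327,2.699
L5,PCp3,1.160,5.007,1.231,2.916
L6,PCy3,1.236,4.181,1.415,2.366
L7,PEt3,1.424,2.620,1.364,1.419
L8,PH3,1.898,3.132,2.140,4.614
L9,PMe3,1.557,2.132,0.608,1.112
L10,P(NMe2)3,1.418,2.880,1.846,1.488
L11,P(OMe)3,1.637,2.555,1.418,1.482
L12,PPh3,1.569,2.873,1.816,1.744
L13,Pi-Pr3,1.330,2.679,1.420,2.193
L14,P(o-MeOC6H4)3,1.366,2.865,1.840,2.948
L15,P(o-tol)3,1.669,4.653,1.640,3.094
L16,P(p-CF3C6H4)3,1.656,2.667,1.421,2.437
L17,P(p-ClC6H4)3,1.618,2.744,1.553,2.020
L18,P(p-FC6H4)3,1.594,2.767,1.592,1.863
L19,P(p-Me2NC6H4)3,1.398,2.985,2.258,2.045
L20,P(p-MeOC6H4)3,1.494,2.892,1.874,1.840
L21,Pt-Bu3,1.415,4.863,1.974,2.282
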