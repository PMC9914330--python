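variable,root1,root2
C14:0,-1.0922,0.8489
C15:0,0.3042,-0.1335
C16:0,0.8185,0.5272
C18,-0.2992,-0.3687
C16:1 *cis*-9,0.2795,-0.1934
C18:1 *cis*-9,0.8031,0.6734
C20:1 *cis*-11,0.1487,0.4687
C16:2 n-4,-0.5911,-0.3427
C18:4 n-3,0.4235,-0.3404
C20:5 n-3 (EPA),-0.8695,-0.0030
C22:5 n-3 (DPA),-0.9837,0.6297
C22:6 n-3 (DHA),0.3468,-1.2826
canonical_R,0.9271,0.7626
eigenvalue,6.1167,1.6384
cumulative_proportion,0.7887,1.0000
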