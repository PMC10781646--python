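# Proliferation / cell-cycle genes (mouse symbols), S and G2/M phases.
Mki67
Top2a
Ccna2
Ccnb1
Ccnb2
Ccne1
Cdk1
Cdc20
Cdc6
Cdca3
Cdca8
Mcm2
Mcm3
Mcm4
Mcm5
Mcm6
Mcm7
Pcna
Birc5
Ube2c
Bub1
Bub1b
Plk1
Aurka
Aurkb
Tyms
Rrm1
Rrm2
Tk1
E2f1
Foxm1
Cenpa
Cenpe
Cenpf
Nusap1
Tpx2
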