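# Immediate-early / stress genes induced by tissue dissociation (mouse symbols).
Fos
Fosb
Fosl1
Fosl2
Jun
Junb
Jund
Atf3
Egr1
Egr2
Ier2
Ier3
Ier5
Dusp1
Dusp2
Dusp5
Klf2
Klf4
Klf6
Nr4a1
Nr4a2
Nr4a3
Hspa1a
Hspa1b
Hspa5
Hspa8
Hspb1
Hsph1
Dnajb1
Dnajb4
Socs3
Zfp36
Btg1
Btg2
Cyr61
Rhob
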