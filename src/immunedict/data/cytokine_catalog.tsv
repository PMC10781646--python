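name	family	ligand_genes	receptor_options
IL-1α	IL-1	Il1a	Il1r1+Il1rap
IL-1β	IL-1	Il1b	Il1r1+Il1rap
IL-1Ra	IL-1	Il1rn	Il1r1
IL-18	IL-1	Il18	Il18r1+Il18rap
IL-33	IL-1	Il33	Il1rl1+Il1rap
IL-36α	IL-1	Il1f6	Il1rl2+Il1rap
IL-36Ra	IL-1	Il1f5	Il1rl2
IL-2	gamma-chain	Il2	Il2ra+Il2rb+Il2rg|Il2rb+Il2rg
IL-4	gamma-chain	Il4	Il4ra+Il2rg|Il4ra+Il13ra1
IL-13	gamma-chain	Il13	Il4ra+Il13ra1
IL-7	gamma-chain	Il7	Il7r+Il2rg
TSLP	gamma-chain	Tslp	Crlf2+Il7r
IL-9	gamma-chain	Il9	Il9r+Il2rg
IL-15	gamma-chain	Il15	Il15ra+Il2rb+Il2rg
IL-21	gamma-chain	Il21	Il21r+Il2rg
GM-CSF	beta-chain	Csf2	Csf2ra+Csf2rb
IL-3	beta-chain	Il3	Il3ra+Csf2rb
IL-5	beta-chain	Il5	Il5ra+Csf2rb
IL-6	IL-6/IL-12	Il6	Il6ra+Il6st
IL-11	IL-6/IL-12	Il11	Il11ra1+Il6st
IL-12	IL-6/IL-12	Il12a,Il12b	Il12rb1+Il12rb2
IL-23	IL-6/IL-12	Il23a,Il12b	Il12rb1+Il23r
IL-27	IL-6/IL-12	Il27,Ebi3	Il27ra+Il6st
IL-30	IL-6/IL-12	Il27	Il6st
IL-31	IL-6/IL-12	Il31	Il31ra+Osmr
IL-Y	IL-6/IL-12	Il27,Il12b	Il12rb1+Il27ra
LIF	IL-6/IL-12	Lif	Lifr+Il6st
OSM	IL-6/IL-12	Osm	Osmr+Il6st|Lifr+Il6st
CT-1	IL-6/IL-12	Ctf1	Lifr+Il6st
NP	IL-6/IL-12	Ctf2	Lifr+Il6st
IL-10	IL-10	Il10	Il10ra+Il10rb
IL-19	IL-10	Il19	Il20ra+Il20rb
IL-20	IL-10	Il20	Il20ra+Il20rb|Il22ra1+Il20rb
IL-22	IL-10	Il22	Il22ra1+Il10rb
IL-24	IL-10	Il24	Il20ra+Il20rb|Il22ra1+Il20rb
IL-17A	IL-17	Il17a	Il17ra+Il17rc
IL-17B	IL-17	Il17b	Il17rb
IL-17C	IL-17	Il17c	Il17re+Il17ra
IL-17D	IL-17	Il17d	Il17ra
IL-17E	IL-17	Il25	Il17rb+Il17ra
IL-17F	IL-17	Il17f	Il17ra+Il17rc
IFNα1	interferon	Ifna1	Ifnar1+Ifnar2
IFNβ	interferon	Ifnb1	Ifnar1+Ifnar2
IFNε	interferon	Ifne	Ifnar1+Ifnar2
IFNκ	interferon	Ifnk	Ifnar1+Ifnar2
IFNγ	interferon	Ifng	Ifngr1+Ifngr2
IFNλ2	interferon	Ifnl2	Ifnlr1+Il10rb
LTα1/β2	TNF	Lta,Ltb	Ltbr
LTα2/β1	TNF	Lta,Ltb	Tnfrsf1a|Tnfrsf1b
TNF	TNF	Tnf	Tnfrsf1a|Tnfrsf1b
OX40L	TNF	Tnfsf4	Tnfrsf4
CD40L	TNF	Cd40lg	Cd40
FasL	TNF	Faslg	Fas
CD27L	TNF	Cd70	Cd27
CD30L	TNF	Tnfsf8	Tnfrsf8
4-1BBL	TNF	Tnfsf9	Tnfrsf9
TRAIL	TNF	Tnfsf10	Tnfrsf10b
RANKL	TNF	Tnfsf11	Tnfrsf11a
TWEAK	TNF	Tnfsf12	Tnfrsf12a
APRIL	TNF	Tnfsf13	Tnfrsf13b|Tnfrsf17
BAFF	TNF	Tnfsf13b	Tnfrsf13c|Tnfrsf13b
LIGHT	TNF	Tnfsf14	Tnfrsf14|Ltbr
TL1A	TNF	Tnfsf15	Tnfrsf25
GITRL	TNF	Tnfsf18	Tnfrsf18
C3a	complement	C3	C3ar1
C5a	complement	Hc	C5ar1
FLT3L	growth factor	Flt3l	Flt3
IL-34	growth factor	Il34	Csf1r
M-CSF	growth factor	Csf1	Csf1r
G-CSF	growth factor	Csf3	Csf3r
SCF	growth factor	Kitl	Kit
EGF	growth factor	Egf	Egfr
VEGF	growth factor	Vegfa	Flt1|Kdr
FGFβ	growth factor	Fgf2	Fgfr1
HGF	growth factor	Hgf	Met
IGF-1	growth factor	Igf1	Igf1r
TGFβ1	other	Tgfb1	Tgfbr1+Tgfbr2
GDNF	other	Gdnf	Gfra1+Ret
PSPN	other	Pspn	Gfra4+Ret
PRL	other	Prl	Prlr
Leptin	other	Lep	Lepr
AdipoQ	other	Adipoq	Adipor1|Adipor2
Resistin	other	Retn	
Noggin	other	Nog	
Decorin	other	Dcn	Egfr
TPO	other	Thpo	Mpl
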