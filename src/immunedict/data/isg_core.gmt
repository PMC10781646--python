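ISG_CORE	curated core interferon-stimulated genes (mouse symbols)	Isg15	Ifit1	Ifit2	Ifit3	Irf7	Irf9	Stat1	Stat2	Mx1	Mx2	Oas1a	Oas2	Oas3	Oasl1	Oasl2	Rsad2	Usp18	Bst2	Ifi27	Ifi44	Ifi203	Ifih1	Ddx58	Ddx60	Zbp1	Cmpk2	Xaf1	Gbp2	Gbp3	Ifitm3
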