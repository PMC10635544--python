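glycosaminoglycan binding	GO set among 514 downregulated genes; reported FDR q 9.3E-04 (display only)	Smoc2	Fgfr1	App	Ccdc80	Tgfbr3	Fstl1	Adamts1	Tpsb2	Thbs1	Pcolce2	Fn1	Cyr61
polysaccharide binding	GO set among 514 downregulated genes; reported FDR q 1.2E-04 (display only)	Smoc2	Fgfr1	App	Ccdc80	Tgfbr3	Fstl1	Adamts1	Tpsb2	Thbs1	Pcolce2	Fn1	Cyr61	Enpp2	Agl
morphogenesis of an epithelium	GO set among 514 downregulated genes; reported FDR q 7.8E-03 (display only)	Fgfr3	Nrp1	Lmo4	Npnt	Smad4	Igf1	Jag1	Pthlh	Igf1r	Sfrp1	Sema3c	Tgif1	Chuk
epithelium development	GO set among 514 downregulated genes; reported FDR q 1.7E-02 (display only)	Fgfr3	Nrp1	Lmo4	Npnt	Smad4	Igf1	Jag1	Pthlh	Igf1r	Sfrp1	Sema3c	Tgif1	Chuk	Gja1	Irf6	Jun
tissue morphogenesis	GO set among 514 downregulated genes; reported FDR q 3.7E-04 (display only)	Fgfr3	Nrp1	Lmo4	Npnt	Smad4	Igf1	Jag1	Pthlh	Igf1r	Sfrp1	Sema3c	Tgif1	Chuk	Twsg1	Fkbp1a	Tpm1	Tgfbr3	Col11a1
positive regulation of cell communication	GO set among 514 downregulated genes; reported FDR q 1.3E-03 (display only)	Fgfr1	Twsg1	Fgfr3	Ube3a	Npnt	Skp2	Smd4	Jag1	Lpar1	Ctnna1	Igf1r	Nras	Gan1	Thbs1	Chuk
positive regulation of signal transduction	GO set among 514 downregulated genes; reported FDR q 4.7E-04 (display only)	Fgfr1	Twsg1	Fgfr3	Ube3a	Npnt	Skp2	Smd4	Jag1	Lpar1	Ctnna1	Igf1r	Nras	Gan1	Thbs1	Chuk
extracellular matrix organization	GO set among 514 downregulated genes; reported FDR q 2.9E-02 (display only)	Smoc2	App	P4ha1	Npnt	TgfbrI	Ccdc80	Col11a1	Serpinh1	Cyr61
proteinaceous extracellular matrix	GO set among 514 downregulated genes; reported FDR q 1.4E-02 (display only)	Matn2	Col4a2	Lum	Npnt	Adamts15	Ccdc80	Sparc	Timp3	Prelp	Smoc2	Gpc6	TgfbI	Tgfbr3	Adamts1	Mfap4	Col11a1	Fn1
extracellular matrix	GO set among 514 downregulated genes; reported FDR q 2.1E-02 (display only)	Matn2	Col4a2	Lum	Npnt	Adamts15	Ccdc80	Sparc	Timp3	Prelp	Smoc2	Gpc6	TgfbI	Tgfbr3	Adamts1	Mfap4	Col11a1	Fn1
negative regulation of apoptosis	GO set among 514 downregulated genes; reported FDR q 1.5E-02 (display only)	Fgfr1	Rock1	Skp2	Bnip3	Birc6	Igf1	Sgms1	Ctnna1	Ube2b	Adora1	Nras	Bfar	Tsc22d3	Agtr1a	Rasa1
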