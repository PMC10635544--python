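Qk
Il11ra1
AU015680
Ccdc80
Sfrp1
Fgfr3
Fstl1
Axl
NA_01
NA_02
Prelp
Lmo4
Fn1
Gpr177
Pdlim7
Cd47
Rfx7
Rnpc3
Chuk
Schip1
Inhbb
Arl6ip5
Gpr177
Htra1
Gatm
Gda
Vldlr
Bpgm
Igf1r
Enpp2
Myadm
Sfrs6
Sspn
NA_03
Maged1
Tgif1
Nktr
NA_04
Gnas
Ttc7b
Lum
1700019D03Rik
NA_05
Gnai1
Gtf3c2
Klf9
Serinc1
Tgfbr3
Zfp280d
Pde4dip
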