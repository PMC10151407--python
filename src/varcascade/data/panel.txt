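# Cataract / lens-disorder candidate gene panel (Cat-Map style).
# One symbol per line; optional tab-separated category.
Cryaa	crystallin
Cryab	crystallin
Cryba1	crystallin
Cryba2	crystallin
Crybb1	crystallin
Crybb2	crystallin
Cryga	crystallin
Crygb	crystallin
Crygc	crystallin
Crygd	crystallin
Cryge	crystallin
Crygf	crystallin
Crygs	crystallin
Cryz	crystallin
Gja3	membrane
Gja8	membrane
Mip	membrane
Lim2	membrane
Epha2	membrane
Chmp4b	membrane-associated
Fyco1	membrane-associated
Efna5	membrane-associated
Prx	membrane-associated
Lctl	membrane-associated
Bfsp1	cytoskeleton
Bfsp2	cytoskeleton
Vim	cytoskeleton
Hsf4	transcription factor
Pitx3	transcription factor
Foxe3	transcription factor
Pax6	transcription factor
Prox1	transcription factor
Yap1	transcription factor
Tdrd7	RNA-binding
Celf1	RNA-binding
Dnase2b	lysosomal enzyme
Galk1	syndromic
Gcnt2	syndromic
Pxdn	syndromic
Agk	syndromic
Ftl1	syndromic
Phyh	syndromic
Grifin	membrane
Kl	membrane
Lgsn	cytoskeleton/chaperone
Bnip3l	organelle degradation
Plaat3	organelle degradation
Cdk1	organelle degradation
Lenep	epithelial
Dst	syndromic
Ush2a	syndromic
Lrp2	syndromic
Bub1b	syndromic
Abhd12	syndromic
Ap4b1	syndromic
Fktn	syndromic
Hspg2	syndromic
Mthfr	syndromic
Casz1	syndromic
Cc2d2a	syndromic
B3gnt4	syndromic
Xpc	syndromic
Igf1r	syndromic
Myo7a	syndromic
Tmprss5	syndromic
Atm	syndromic
Lamb2	syndromic
Col18a1	syndromic
Gemin4	syndromic
Nrcam	syndromic
Ltbp2	syndromic
Adamts10	syndromic
Neu1	syndromic
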