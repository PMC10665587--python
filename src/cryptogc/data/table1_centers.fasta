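>P16066 ANPR-A atrial natriuretic peptide receptor 1 predicted GC center
RYCLFgdtVntasR
>P20594 ANPR-B atrial natriuretic peptide receptor 2 predicted GC center
RYCLFgdtVntasR
>P40617 ARL4A ADP-ribosylation factor-like protein 4A predicted GC center
SFHIVilgLdcagK
>Q02108 GCYA1 guanylate cyclase soluble subunit alpha-1 predicted GC center
RYCLFgnnVtlanK
>P33402 GCYA2 guanylate cyclase soluble subunit alpha-2 predicted GC center
RYCLFgnnVtlasK
>Q02153 GCYB1 guanylate cyclase soluble subunit beta-1 predicted GC center
RYCLFgntVnltsR
>O75343 GCYB2 guanylate cyclase soluble subunit beta-2 predicted GC center
RYCLFgdtVntasR
>P25092 GUC2C guanylyl cyclase C, intestinal, predicted GC center
RYCLFgdtVntasR
>Q02846 GUC2D guanylyl cyclase 2D, retinal, predicted GC center
RYCLFgdtVntasR
>P51841 GUC2F guanylyl cyclase 2F, retinal, predicted GC center
RYCLFgdtVntasR
>Q9Y616 IRAK3 interleukin-1 receptor-associated kinase 3 predicted GC center
SFGIVimeVltgcR
>Q13387 JIP2 C-Jun-amino-terminal kinase-interacting protein 2 predicted GC center
SFGLFsclVngeeR
>Q6ZRQ5 MMS22 methyl methanesulfonate-sensitivity protein 22-like predicted GC center
SYTIFlciLakvvK
>O95563 MPC2 mitochondrial pyruvate carrier 2 predicted GC center
KWGLVcagLadmaR
>A0A3B3IT52 MSD5 putative uncharacterized protein predicted GC center
KYHIVskaIaqrlK
>P04629 NTRK1 neurotrophic tyrosine receptor kinase 1 predicted GC center
SFGVVlweIftygK
>Q96KN7 RPGRIP1 X-linked retinitis pigmentosa GTPase regulator-interacting protein 1 predicted GC center
KFTVVsdpLdeekK
>Q9HBT7 ZN287 zinc finger protein 287 predicted GC center
SYGIVhrkIlpgeK
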