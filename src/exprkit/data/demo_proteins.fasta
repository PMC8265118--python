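>sp_positive_0
MNRRFLLVAMLIMLILIVAQAETQPPHDVYYHKQDQKVCYWTKHMVNKTGYDDDSQNQTV
C
>sp_positive_1
MKAIMIFVVAIFMTTANAKMLKKDPRKPEKNMTTSEDYAKDSNNEERFYKDLNKYQVL
>solubility_gradient_0
FCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFC
FCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFCFC
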