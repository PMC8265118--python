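>random_cds_0
ATGCAGGTAATATATTCAATCATCGTTATGCACAAATCTTATAACGCTTACATGCCCAAC
GGTAACTGCAGCCTCCGAGGATCGTTCTCTTAA
>random_cds_1
ATGTGTTCTATTAACTATCGCGCAGAATACGCCGATAATTCTATTCAATGCAACTGGTGC
GCGACGGAAAGCGTGCAGCATTGGGATGTGTAA
>random_cds_2
ATGACGCACCAATATTTACACCATCTCTCCCAGTTACGATGTTGGTTCCCGATGATCAAA
TCTCGCGGACACTTGCCACATCAGGCATACTAA
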