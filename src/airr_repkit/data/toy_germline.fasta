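>TOYV1-1*01
TCACGAAGATCCCTCGGTAGAAGTAAGGCGACATACAGTAATCGCTTTGAATACCATAACTGTCTAGAT
>TOYV2-1*01
TCATATGTTAGCCACGAGGCAAGTTTGGAGACTCTTCTGATAAGTAAAGTTTCAGAGTCATGTGGTGTCCGTAAA
>TOYV3-1*01
CGAAGTCCCAGAAATTCCCTCGCTAGCAAATACATAAGCCGGCGCATGCGAATCGAACGATGTCTACGA
>TOYV4-1*01
GGCGATGGACCCAGGACACTGGGCCACAAGGCTCGCACGCGTTACCGCCGAGGCTATACGTGTAACGCT
>TOYD1*01
CTAGGTACTCGA
>TOYD2*01
GCTGAGAGCCTTCCG
>TOYD3*01
AGTGCCGTACTACCGATC
>TOYJ1*01
ATTCAACGGAAATACGTATGGTCAACGGTAGTC
>TOYJ2*01
GGTGCGCAGACCCCGTGGGGTCGTGACGCTTCT
>TOYJ3*01
ATTTCTCCGCACCCTTTATCTTGGCAACCTGAC
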