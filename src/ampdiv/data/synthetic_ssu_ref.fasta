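>synthetic_16S_reference synthetic stand-in for a full-length 16S rRNA gene reference
TGTCACCATAATCGTCGACCAGTAAATTGATACTTTCCACGCTTAACCATTGGGTCCTCAAGTAGGAGGA
TTGAGCGTTATGCCGATAGTGTTTGAGCTGAGGGCGTACACAACTACAGAGTTTGCCTAAACGTTCCGGG
TGGATAAGATCTGCAGTAAATCCTTACCGCCAGAATAAACGGGCTTTGCATAATACCATCGGTCCTCGTT
CACAGAGAGGTTAGGCATTTTGCTGGATATCGGGACAGGGCCTTAAGAGCTGTGTCGTTAATCGCTACAC
CCACGCACATCGAGTTTCGGCCAACTCTCGCACACCAATGTGGTCACCTCGTATCTTGGTTCTGAGTGTT
TTATCCCCGTAGAAAAAGATCGCCGACGCAATTTCAACGTTACAGACAAACTGGAGGGATCTATGCAGTT
ACAACTACCAAACGTTTCTGTCGGTCGTGTCTCCAGGGCAAATAATAGTTTTCCGGGATCACTGTACAAG
ATCTAAGCATATGTGGCCACAGTATTTCCCTATACGTGGTGGTGGGAAGCGTCCACTTCCTAGGATACGG
TCGGCCATCGTGCTAGTGCCTAAGGTAGCATTAAGACCCTGCTGTGTTGCAAGCATCTCGCAGTTAAGCT
AACCCTGACCCCTGCTGGCAGGGGAGCTGCTGCCATCTTTTTGCGATGTGGGAAGCAGAAGTCGAGTCAA
AAGCACAGGGTCGGGTGCATAAGTAGTTTCCTTAAGGGACAGGCGCACCATCCTAGAAGTGTGCCAACCA
GAGGGGCCAATGCACATAGTTCCAAAGCATTACCAGAGGCTCCGACTAGAGAGCGCCACCGGGGATATCT
GCAGTCCAAGTTCTGTGTTAAGCCGCAAACAGTATACACAACGGTACTGGCCGGTACCCTACCGTAGCAC
TTTTGATCTTCGAAGTATGAACCTTCATTTCTACCGTATGGGGCAATCCGCGGGCGCAACAACAAGCGAC
TACGACTTGAGCTCGGTGGTCTTCGCGCTACCATCATCGGCCCGCAGTAAGTTAAATACTGGGGTCCATG
GGTAAAGCTAAACCACTTAAGAAGGGCAGCAACGCTCGTCCTACGTATAGTTGTTCTCCTATAAAGGGCC
GCCGTTCGGTTCAAGACGATCGAAGATTAAGGCACTGACCATCCTTGGACGATCCAGGTACGGCAGATTG
GTGACAAGGATCATATTTTGAAAATCCGGTGCACAGTACCTTTATAACGTGAATGCCATGGCAACCCGCC
TCAAACCCCACTGTGAAGGACGGGCAGCTTAACCCTCGATATGCTGATGCACAGCCGGGTTTAGACACTC
CCTTTGGGTTTCGCGGTTGGAATCTTCTAACTCGCCACCTATCGTGGGGTAAAGCGACCCTAACCAGAGC
TCGCGCCGAGCCGCGTTTACAAAGATCCGTAGCCATTTAAACGGACTCACGT
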