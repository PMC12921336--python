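>chr1
CCGGAAGCGTAGCCCTATCCTGCCACAAAGGACCTTCGATGAAACGGTTAGCGGTCTACAATTAATGGGG
AGCTTCCTTTTTCCTATAGACACTTAAAAACAGTTTGGGGGCTCCTGTTTCAAGCAGAAACCTGGCGACA
GCCTAAAAGCGGGACGTTTGGCTACGTGAAACTGCTCGCTCAACGGACTTCTTTGCTAGTTCATAGCAGA
CTTTATCTTGGGATGTTGGTGTGTATCGACTGTCACGCGCGGGGGTGTCCACAATCCATCAACTTAAGAA
CGATGGAGCATGTTGCGGCATCACAAGTAGCTAAGGCACGCGTTAGCGTTCGGCCCGAGCTCCCGGGCTC
TCACTTGGGGGGGAACGTGAGTAGTCCAGCTTCGTAGCCACTTAATAAAGCTAGGAATTCTTCCATCAGC
GTCAGGCTTAGCTCTGGGAAGTAGCAGTGGGGGGAGTAAGGCTTTTTACGCGGGGTCGGTAGCCCACGCC
AGGCATGACCAGAGGTAAACTATTTAGTGATATAGTGGTGAGCCATAACCGGATAAAGTCCGGACCTTGC
TTTATTAGTTGCGAGATGTTCCTACACTAAACAACCTGGACCGTTTGTGGTTTGGAATAGCTGCCCTGGA
GAACCAAGGGGTGTAGACTCAGGGTCACTTTGAGACGCGTTAAGGGTGTAAACACAGGTCGTTAGGACCG
AGCTAGGCCATTCAGGCGGTGTGATGTAGCGAAACTGAACCATTCGGTTTGCACTCTAATTTCGCGTTCT
GACACCCAATAGCGACAGACGAACGTCGTCAGGGCGCTGGCCTTCTTCTAACTGACTCACGTAAGGGGTC
ATTGTAGGCCGAGTTAACTAGGAACGCTTAGCAGTACCAGGGTCATGGGACGGAGGGTAACGAGCTTTTG
CTGTTGCAAACCCTATTGCGTACACAAAATCACGTGAGCGTTCAATTCAAGTTGCCTGGTCAGGGGAGTA
CCTTCCAACTCGTGCCCGTGATCGCTGAACTAGCACGCGGTAAAGATATTCCCTAGCGGCGTCACGTAAT
TGTAGTGGCCTACCGCAAGCTCTGATGCAGAGGACGGTCCAGTCATTTAATCATTACGTGTGATAAGGTC
TAGACACTAGGAGGCGACTCCAGGACTGTGGCAGCGCAGGAACGAACATTTGACCTGGACTACCTGTAGG
ATATATCCAGTGGTAAATGATGCGTCAGAGTACCGCCCACCATGCTCCAGGGTCTCCCCGCAAGTTTGTC
CTAGACGTAAAGTCTGTGTGAAGCTTATCAAACGATGTTATGACCCCTTAAGTCGGCAGCAGTGTCCCTG
TTGGCCGGCACCAAGGTGCCTTGTCTTGACACAACGGTGACCAGTCCGCCCGGAGACATTTCAATTCCCG
AAAGCATACTAGTCAAATCTAACCAGGACGTGAGAAACGTTGTTACCCAAAAAAGGGAGGTCTATTATCT
GTGCGTAACCTATACAGACTGGAAGGCACTGCCTGACCCTTAGCCCAATGTCAGTCTGCCGAATGGCAAG
TCGATGAATAGGTCGTTGACGACTTTCTCGAACGGTGCGCTGGTAACTTTGGTAACCCAGGTACATCACC
TCAAGTCCTAATTAGCCCTAGGGTTCTGTAAACATTCGCCATTACAGTAATAGGCCGCTTCGGTAGTAAT
TGTTCCCCGACTCAGGTCGGCATCTTCAATTCCTTTGGGGAGTTAAGCACGGTGCCGGGTAGGCCATCTA
ATGATGTGTCACCGCAGAACGGCGACGCATATGACTAGAGGTCGCGTCTAGTCTAGCGCTGATCGGTGGG
CTCAGAAAAGAATCGCGGCGGGTTTGGGGAACAGAGGAGCCCCACTGAGCCCAGTGAGGAAAATGTAATG
CACTACGGGGCACACCGTGCGGTATTCATATGCTCGTCGTAAGTGAAGCTCTAATCCTGGTAAGGCTCCC
CGCGATGACTCTCTTCCCTCCCATGGTCATGAATGGCAGATTAGCACAAGTTTATACCCAATTAGATGCA
TGTTTCCGCCAACCCCGGGTTACCCCAGACCCTCGTTGGTTATTAGAGGAATTGTGGAATATCCTGGAAA
AGTCGAGTTCCACAGCCATATGAGCGACTGAGTCATATTCGGTAGTTGCTATGGAGTGGCCATTCGCGAG
GTTAAATCGGGGATGTAAGTAAGCTGACAA
>chr2
ACTTCTACCCATTTGCTGTTCGGATCCATAAACAGTGAACTTCTCAGGCCGTTGATAATACTCGAGAGTA
TACCATTTAATAACTTAGTAATCCTTGTAACATGGATGGCATGTCTGCTGGATTAATGAAGCTAAGCGTG
AGCGACGGTGCAATTAGGAGTGGGCATAGAGAACTTCGTTAACAGGTTGTACGCTGGCCCCCTTCCCATG
AGCTATGGACTACAGACGTGCGTGGTCAAAAAACAGATTCCTCTCATTGCTTCGGCATTGCTTTTTGCCA
AGCGGCGTGAAGACAAATGTAGGCCTTTCCTGTTAGTTCGATTATTAAGAGCAATTAGCTACGATCGGGC
AATCCAGACAATTCGATACCTGTTGTATCGTTCTCGTGTACACATGGATCGGGACGGGACTTGGGCAACT
GTTACCGGAAAGAGCCACAGTGCCAGGAAGGCGTATATCATTAACTGGTGCGATACCTATCCAACCTCAG
ACCCTATCTCAGCCAATCAGTCCATCCTCCGCCAGCGGATAATGGGACTTTGCATAAGAAGGTCCCCAGA
GTGGGGTTAAGATTGGGCCCCTTTGAATGCGGGTCCTAAGCTCCCTCGTGCTGACGAGATGGGGTAAGTA
GGACAACATCACGTTTTTGCAAGCGCCCACGTTCTCTAGTTATATTCCCATGGTCCTCAAAGTAATGAAC
AACCAGGTGACCACTGTGGTACACGCCTGATAACCAGCTGCTAAATCGCTTTTAGTCGTTCGACCCGCCC
TGGACCTCATGCACCGATGGCACGTAATAGCATAAATCGCAGCGCTTTTGAGCCACATATTTGCACGAAT
TTAGAAATCAGCTTCTAATCAGGCGAGGTAAGATATGTTGACTCTATCGAGTCTCCCCTACATGTGGGCT
CTCATAGTAACACAGCCTATACTCTGCGGAATGTTGCCATTCCTTAGTTAGTTGAACGAGTCAACGGCCT
AAGGCTGCTAAAGCAGGAAGCGGGTTGTCACCAAGGAGATCGTCCCAGCTCGGAAGAAACATCTCCAGGG
ATGTCGTCAGCAGAACTGTGGTAACAGAGTTGCCAAAAAGTCTCCGTATGCATTAGTCTTTCCGGACGAT
GGCCAGCTTTGGCACCTAAAACCTTGTATAAATAGGGCGGCAGGATTTCATGGGTGTCTACCAACTGGAA
TACGGTATAACATGTGAGCTGAAATTGCTAAAAGACAGATCCGTGTTAAAGCGGGCTACAGGAGGCCCTC
AGATAGTTATGTGCATGGAGTGCCGGCCCTACCCCCGGGAGTATGCCGCATACTACCTCGACCAACTAAC
CCCGTGGCCGAGCCTTTTGTATTATTAACTATTTTGTTGCTTCCCCTCGTTTAGGCCTCGGCGAGTCGAT
ATTCCGTTCGGCGGTGTCGCAAAGCACACTGGAACTTCATTTGCGACGCGGGGTCGTCGATGAATGACCA
GTGGTCGCTCAAAACATCCCTGTCATATGCGGGGAACCAGGCGCCTGCGTAGAGCCACCTCCGGATCTGC
CAACCAATGAACTAAGGGTTCGCTAGTCACGGAGCTATTTCCTCACAGCATGAATACCCGGGGTTCGCAA
CTCCATCCGCTGGGAAGTAATAGCTAGCCCGGTGCTTATGGAATACGAGCTCGCTACCAAGCAGGCGACA
AAGGTGCTGTCGACCCTGGAGCTGGGGAACTGGACTATGCAGCTGAGCCCCCAGATAGAAATCGGCGCCT
CGGATGTATGTAAGTAGATGCCGTACTGCCATTCGACGGTAGGACCGTGT
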