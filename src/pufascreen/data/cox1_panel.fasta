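>cox1_panelA_rotaria_like
ATCCTCAGACGCTTTATCCTCAGGTATGCTCTCCTCCATCGTGTCACTAACAGATAGCATAGAAGGGTGT
ACTTGTTGTCTTCAGGGTGAGGTACCAGCCATTAACATACAATTCGCTCGCCCCGGCACGATTAATGGAC
CGACCAGGGCGAGAGAAGTGGGACTCGAAGCGTCTATCAACCCGCGTCGTGCTTTATAAGAATTCAGGCC
CCTCGAGTGAGCTAGGGAAAATTGATGCCATGATATTTGAGATCACACTCCCTGGTCACTATAGGACACA
CTCGAAGCACTGCCTTCCTTAGGATTCAGGATTCGATGGAACTTTATCCCTGGTATATGCTACTGTTTTG
TGTAGCTATATCCGCTGTATCTAAATCAGCTCAGACGCATTAGGCATGATCGCCAGGAGGCTTGTGAGGC
GAACGTACTGCAAGATTTATCTGCTATGGAGGGAATTGGCTGCTTACTATGAGGGTTATGCCTACGCTCG
GGACGATTTGGGGTTGAGTAAAATCGGTCATGAGTCGTTACTAGCGTTGTTAACACCGGCTTAAACCTGG
TTGTGGGCCGCTGCACCTTTCCCGGGGTGGCTATTCAGCTGTCAAGAGGCATCTGATATGACGCTATCAT
AATGCTTGGACTATCATTCGTGTCGCAG
>cox1_panelB_rotaria_like
ATCCTCAGACGCTTTATCGTCAGTTATGCTCTCCTCCATCGTGTCACTGATAGATCGCTTAGAAGGGTGT
TCTCGTTGTCTTCAGAGGTAGGTACCAGCCATGAACATACAATTCGCTCGCCCCGGCAAGATTAATGGTC
CAACCAGGGCATGGGAAGTGGGAATCGAAGCCTCTATCTACCCGCGTCGAGCTTTATAAGAATTCAGGAC
TCTCGAGTGAGCTAGGGAAAATTGATGCGATGATATCAGAGATCACACCGCCTGGACACTCTAGGACACA
CGCGAGACACTGCGTTCTTTAGGATTCAGGATTAGATGGGACTTTATCCCTGGTATAGGCAACTGTTGTG
TGTAGCTATTTCCGCTGTATCTTAATCAGCTCAGACGCATAAGGCATGATCGCCAGGAGGCTTGTGATGC
CAACGTACTGCAATATCTATCTGCTAGGAAGGGAATTGCCTGCTTACTATGATGGTTATGCCTACCCTCT
GGAAGATTTGGGGTTCTGTAAAGGCGGTCATGAATCAGTACTAGCGATGTTAACACGGGCTTAAACCTGG
TTCTCGGCCGCTGGAACTTTCCCGGGGGGGCTCTTCAGCTGTCAAGAGGCATCGGTTATGAGGCTATCAT
CATGCTTGGTCTATCAGTCGTGTCGAAG
>cox1_panelC_adineta_like
ATCCTTGCGCGCTAAATTCACAGCTATGCTGTCGCTCACCATGTCACAAGCAGATATCATGGAAGGTTGT
ACTTATTGTATCAGGCTGGAGGTACCAACCATTAACATACAATTCGCCCCCCCAGGCACGATCACAGGTC
CGGCCAGGGCGAGAAAATTTGAACTTAATACGTCTATCAACCCGCGTCGTGGGTTATAGCACTTCCAGCT
CCTCGAGCGAGCTAGGAAAAACTCTTGTCATGAGATTTGAGACCACAGTACGTCGTCCCTGTAGAGCTCA
CTCTGAGCTTGGCCTTCCTTATGATTAAGGATTCGATGGATATTTATCCATTGCCTATGCCGCGGTTTTG
TGTAGCGCGCGCCGCTATATCGAAATCAGTTGAAACGCATTAGGCATAATGTCCAGCAGGCTTGTGAGGC
AATCGGAGCGCTAGGTTTTTCTGCAATGGAGGTGTTTTGCTGCGTACTATTAGGCTTATGGCTCGGGTAG
GGACGATTGGGAGTCGACTGAAACCCGTCAGATGGCGTAACTACCGTTATTAGCACCGGCTAAAACATGC
TTGTAGGCCCCTGAGCTTTTCCCGTTGTGCTTATTCTGCATTCAAAACGCATCTGTTATGACGCTTTCAA
AATCCATGGACTACCGATCGTGTCGCAG
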