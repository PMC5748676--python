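>sno001
GTCTATGATGATGTGATAGCATTTCTGCCAAAATTCTGATGCATTCGTTACCCAGTGATG
ATCCTCACGAAACACAGGTGATGACCTTCTCTGATCGG
>sno002
GTCTATGATGATGTGATTGCATTTCTGCCCAGATTCTGATGCATTCGTTACCCAGTGATG
ATCCTCACGAAACACAGGTGATGAACTTCTCTGAACGG
>sno003
GTCTATGATGATGTGCATGCATTTCTGTCAAAATTCTGATGCATGCGTTACACAGTGATG
ATCCTCACGCAACACAGGTGATGAACTTCTCTGAACGG
>sno004
GTCTATGATGATGTGATTGCATTTCTGCCAAGATTCTGATGCATTCGTTACCCAGTGATG
TTCCTCACGAAACACAGGTGATGAACTTCTCTGAACGG
>sno005
GTCTATGATGATGTGATTGAATTTCTGCCAAGATTCTGATGCATTCGTTGCCCAGTGATG
ATCCTCACGAAACACAGGTGATGACCTTCTCTGAACGG
>sno006
GTCTATGATGATGTGATTGCATTTCTGCCAAGATTCTGATGCATACGTTACCCAGTGATG
ATCCTCACGAAACACAGGTGATGAACTTCTCTGAACGG
>sno007
GTCTATGATGATGTGATTGCATTTCTGCCAAGATTCTGATGCATTCGTTACCCAGTGATG
ATCCTCACGAAACACAGGTGATGGACTTCTCTGAACGG
>sno008
GTCTATGATGATGTGATTGCATTTCTGCCAAGATTCTGATGCATTCGTTACCCAGTGATG
ATCCTCACGAAACACAGGTGATGAACTTCTCTGAACGG
>sno009
GTCTATGATGATGTGATTGCATTTCTGCCAAGATTCTGATCATTCGTTACCCAGTGATGA
TCCTCACGAAACACAGGTGATGAACTTCTCTGAACGG
>sno010
GCCTATGATGATGTGATCGTATTGCTGCCAATTATCTGATGCATCCTAAAACCAGTGATG
ATCATCAGTATAGCCAGGAAATGGACTTCTCTGAAGCG
>sno011
GCCTATGATGATGTGATCGTATTGCTGCCAATTATCTGATGCATCTTAAAACCAGTGATG
ATCCTCAGTATAGCCAGGAAATGGACTTCTCTGAAGTG
>sno012
GCCGATGATGATGTGATCGTATTGCTGCCAATTATCTGATGCATCTTAAAACCAGTGATG
ATCCTCAGTATAGCCAGGAAATGGACTTCTCTGAAGTG
>sno013
GCCTATGATGATGTGATCGTATTGCTGCCAATTATCTGATGTATCTTAAAACCAGTGATG
ATCCTCAGTATAGCCAGGAAATGGACTTCTCTGAAGTG
>sno014
GCCTATGATGATGTGATCGTATTGCTGCCAATTATCTGATGCATGTTAAAACCAGTGATG
ATCCTCAGTATAGCCAGGAAATGGACTTCTCTGAAGTG
>sno015
GCCTATGATGATGTGATCGTATTGCTGCCAATTATCCGATGCATCTTAAAACCAGTGATG
ATCCTCAGTATAGCCAGGAAATGGACTTCTCTGAAGTG
>sno016
GCCTATGATGATGTGATCGTATTGCTGACAATTATCTGATGCATCATAAAACCAGTGATG
ATCCTCAGTATAGCCAGGAAATGGACTTCTATCTGAAGTG
>sno017
GCCTATGCTGATGTGATCGTATCGCTGCCAATTATCTGATGCATCTTAAAACCAGTGATG
ATCCTCAGTATAGCCAGGAAATGGACTTCTCTGAAGTG
>sno018
GCCTATGATGATGTGATCGTGTTGCTGCCAATTATCTGATGCATCTTAAAACCAGTGATG
ATCTTCAGCATAGCCAGGAAATAGACTTCTGAAGTG
>sno019
GCCTATGATGATGTGATCGTATTGCTGCCAATTATCTGATGCATCTTAAGACCAGTGATG
ATCCTCAGTATAGCCAGGAAATGGACTTCTCTGAAGTG
>sno020
GCCTATGATGATGTGATCGTATTGCTGCCAATTATCTGATGCATCTTAAAACCAGTGATG
ATCCTCAGTATAGCCAGGAAATGGACTTCTCTGAAGTG
>sno021
GCCTATAATGATGTGATCGTATTGCTGCCAATTATCTGATGCATCTTAAAACCAGTGATG
ATCCTCAGTATAGTCAGGAAATGGACTTCTCTGAAGTG
>sno022
GCCTATGATGATGTGATCGTATTGCTGCCAATTATCTGATGCATCTTAAAACCAGTGATG
ATCCTCAGTATCGCCAGGAAATGGACTTCTCTGAAGTG
>sno023
GCCTATGATGATGTGATCGTATTGCTGCCAATTATCTTATGCATCTTAAGACCAGCGATG
ATCCTCAGCATAGCCAGGAAATGGACTTCTCTGAAGTG
>sno024
GCCTATGATGATGTGAACGTATTGCTGCCAATTATCTGATGCATCTTAAAACCAGTGATG
ATCCTCAGTATAGCCAGGAAATGGACTTCAATCTGAAGTG
>sno025
CCCGATGATGAGGTGATCGGATTGATGATATGTATCTGATGTATCGGTTACCCAGTGATG
ATCCTCACTATGGGTAGGTCATGCACTTCTCTGAGTGA
>sno026
CCCGATGATGAGGTGATCGGATTGATGTTATGTATCTGATGCATCGGTTACCCAGTGATG
ATCCTCACTATGGGTAGGTCATGCACTTCTCTGAGTGA
>sno027
CCCGATGATGAGGTGATCGGATTGATGATATGTATCTGATGAATCGGTTACCCAGTGATG
ATCCTCACTATGGGTAGGTCATGCACTTCTCTGAGTGA
>sno028
CCCGATGATGAGGTGATCGGATTGATGATATGTATGTGATGCATCGGATACCCAGTGATG
ATCCTCACTATGGGTAGGTCATGCACTTCTCTGAGTGA
>sno029
CCCGATGATGAGGTGATCGGATTGATGATATGTATCTGATGCATCGGTTACCCAGTGATG
ATCCTCACTATGGGTAGGTCATGCACTTCTCTGAGTGA
>sno030
CCCGAAGATGAGGTGATCGGATTGGATGATATGTATCTGATGCATCGGTTACCCGTGATG
ATCCTCACTATGGGTAGGTCATGCACTTCTCTGAGTGA
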