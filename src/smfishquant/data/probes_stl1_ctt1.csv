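STL1,CTT1
CAGTGACTGGTTCTGCTTAT,CAGTGACTGGTTCTGCTTAT
TGTCTGTCATGATCGCCATT,TGTCTGTCATGATCGCCATT
GAACCTGCGAAACAACCTAA,GAACCTGCGAAACAACCTAA
TTCACCGCAGAACATAACGA,TTCACCGCAGAACATAACGA
TACGGAACCCATCAGGATTA,TACGGAACCCATCAGGATTA
CACGAAATGCGCATGTAGAA,CACGAAATGCGCATGTAGAA
TCCGATGATAAACTGGCCTA,TCCGATGATAAACTGGCCTA
TTCTGATTGCCAAACGGGAA,TTCTGATTGCCAAACGGGAA
GCAACCCTCTATTTTCAGCT,GCAACCCTCTATTTTCAGCT
CACTGAACAGAACTGTTGGT,CACTGAACAGAACTGTTGGT
CAGGAAGAGAGCAAAAACGA,CAGGAAGAGAGCAAAAACGA
GTGGCGATTCAGGTAGTTTA,GTGGCGATTCAGGTAGTTTA
GTTAACAGCATCGTGAAGCA,GTTAACAGCATCGTGAAGCA
CAATCAAAGCCCTCTGAAGA,CAATCAAAGCCCTCTGAAGA
GCAGCGTTACAACCAGTAAA,GCAGCGTTACAACCAGTAAA
CCCCACCTATGATCATTGAT,CCCCACCTATGATCATTGAT
AGCTTACGTCTACCTAGCTT,AGCTTACGTCTACCTAGCTT
TTGACCTGTGGCACCTAATA,TTGACCTGTGGCACCTAATA
GCACCTCTTGCGTTTTCTTT,GCACCTCTTGCGTTTTCTTT
TGGTGGGTATATCCATGGTA,TGGTGGGTATATCCATGGTA
CGTTTGTTGATGCACGAACT,CGTTTGTTGATGCACGAACT
CCGCAAAGTTACACAACCAA,CCGCAAAGTTACACAACCAA
CAACCGGACTGTCCAATAAA,CAACCGGACTGTCCAATAAA
GATGATGTCGATTTCCTCCA,GATGATGTCGATTTCCTCCA
GGATAACTTGGGCAAATGGT,GGATAACTTGGGCAAATGGT
CTAGACGAATTATCGCCGTT,CTAGACGAATTATCGCCGTT
TACCGCAACTTCTTACCCGT,TACCGCAACTTCTTACCCGT
TCAACCCTTGGTCGTATCCA,TCAACCCTTGGTCGTATCCA
GCAATTGTGGAACCTTCTAA,GCAATTGTGGAACCTTCTAA
CTTCTGTTCGACTTTGAGAA,CTTCTGTTCGACTTTGAGAA
ACAGTGAATGTTTCTCGTGT,ACAGTGAATGTTTCTCGTGT
GACCAAGCATGCAAATGTAA,GACCAAGCATGCAAATGTAA
AGTGCCATCCTCGTATGCTT,AGTGCCATCCTCGTATGCTT
CGTCATAAGAGCCCAATGCA,CGTCATAAGAGCCCAATGCA
CCAAAGTCCTCTTTTTCCAT,CCAAAGTCCTCTTTTTCCAT
GAAGCCCGTCATAGATGCGA,GAAGCCCGTCATAGATGCGA
GTTGAACTGTTTACCAGTAA,GTTGAACTGTTTACCAGTAA
CAACCCAAAATCAATCCAAT,CAACCCAAAATCAATCCAAT
CTGTTATAACTTCCTCATCA,CTGTTATAACTTCCTCATCA
AATAGTAGATAAGGCGTAGA,AATAGTAGATAAGGCGTAGA
TCAGGGTAGAAAAAGAAGAT,TCAGGGTAGAAAAAGAAGAT
TTATAGGTGTCTTCTACTCT,TTATAGGTGTCTTCTACTCT
CGTTCACTGTATCTTCATTT,CGTTCACTGTATCTTCATTT
GGACCTGCCTCTGGAGAACA,GGACCTGCCTCTGGAGAACA
GCCTTTGAAATTCGATAATT,GCCTTTGAAATTCGATAATT
GAATAATACAGTAGAGTAGT,GAATAATACAGTAGAGTAGT
CCAAAGAATGTAATGAACAA,CCAAAGAATGTAATGAACAA
AATTCATAACAGCAAAAAAT,AATTCATAACAGCAAAAAAT
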