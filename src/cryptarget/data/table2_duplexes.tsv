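mirna_id	target_id	target_region_3to5	pairing	mirna_seq
novel-m3234-5p	MRNA_015181_1	AGGUGGGGCCGGAAGUACCU	||||x||||||x||x||||x	UCCAGCCCGGCGUUGAUGGC
novel-m3234-5p	MRNA_002832_2	AGGUACGGUCGCAACAACCG	||||xx||o||||||x||||	UCCAGCCCGGCGUUGAUGGC
novel-m3234-5p	MRNA_011802_2	AGGGCGGGUCGAAACUACUG	|||x||||o||x||||||o|	UCCAGCCCGGCGUUGAUGGC
novel-m3234-5p	MRNA_016177_1	AGGUCGAGCCGCUGCUACAG	||||||x|||||xo||||x|	UCCAGCCCGGCGUUGAUGGC
novel-m3234-5p	MRNA_009453_1	GGGCGGGGCCGCAGCUACCG	o||xx||||||||o||||||	UCCAGCCCGGCGUUGAUGGC
novel-m3234-5p	MRNA_016908_2	AGGUCGUGCCGCAACAACGA	||||||x||||||||x||xx	UCCAGCCCGGCGUUGAUGGC
novel-m3234-5p	MRNA_015275_1	AGGUCGGGCCGGAACGACGA	|||||||||||x|||x||xx	UCCAGCCCGGCGUUGAUGGC
novel-m3234-5p	MRNA_015277_1	GGGCGGGGCCGCAGCUACCG	o||xx||||||||o||||||	UCCAGCCCGGCGUUGAUGGC
novel-m3234-5p	MRNA_004590_1	AGCUUGUGCCGCAACUACUG	||x|o|x|||||||||||o|	UCCAGCCCGGCGUUGAUGGC
novel-m3234-5p	MRNA_000829_2	AGGCAGGGCCGCAACAACCC	|||xx||||||||||x|||x	UCCAGCCCGGCGUUGAUGGC
novel-m3234-5p	MRNA_023160_1	CGGUCGGGCCGCAACUGCUA	x|||||||||||||||o|ox	UCCAGCCCGGCGUUGAUGGC
novel-m3234-5p	MRNA_019284_2	AGGACAGGCCGCAACUUCCA	|||x|x||||||||||x||x	UCCAGCCCGGCGUUGAUGGC
novel-m3234-5p	MRNA_002345_1	AGGUCGAGCCGCAACAGCCG	||||||x||||||||xo|||	UCCAGCCCGGCGUUGAUGGC
novel-m3234-5p	MRNA_011058_1	AGGUGGGGACGCAGGUACCG	||||x|||x||||ox|||||	UCCAGCCCGGCGUUGAUGGC
novel-m3234-5p	MRNA_029442_1	GGGUCGUGCCGCAACUUACG	o|||||x|||||||||xx||	UCCAGCCCGGCGUUGAUGGC
novel-m3234-5p	MRNA_027449_1	AGGUGGGGCCGCUACCGCCG	||||x|||||||x||xo|||	UCCAGCCCGGCGUUGAUGGC
novel-m3234-5p	MRNA_024988_4	AGGGAGGGCCGCAACUUCCC	|||xx|||||||||||x||x	UCCAGCCCGGCGUUGAUGGC
novel-m3234-5p	MRNA_018753_1	GGGUCCGGCCGCAUCUACCC	o||||x|||||||x|||||x	UCCAGCCCGGCGUUGAUGGC
novel-m3234-5p	MRNA_002528_2	AGGACGCGCCGCAACUGCCG	|||x||x|||||||||o|||	UCCAGCCCGGCGUUGAUGGC
novel-m3234-5p	MRNA_002464_1	AGGACAGGCCGCGACUACCA	|||x|x||||||o||||||x	UCCAGCCCGGCGUUGAUGGC
novel-m3234-5p	MRNA_029364_1	AGGUGGGGCCGAAGCUAGCG	||||x||||||x|o|||x||	UCCAGCCCGGCGUUGAUGGC
novel-m3234-5p	MRNA_028783_4	AGGUCGGGUCGCAACUACGA	||||||||o|||||||||xx	UCCAGCCCGGCGUUGAUGGC
novel-m3234-5p	MRNA_015378_1	AGGUCGAGCCGUAACUAGUG	||||||x||||o|||||xo|	UCCAGCCCGGCGUUGAUGGC
novel-m3234-5p	MRNA_028906_3	AGCUAGGGCCGCUGCUACCG	||x|x|||||||xo||||||	UCCAGCCCGGCGUUGAUGGC
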