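name: vh3-vk1-surrogate
h3_length_range:
- 3
- 18
frameworks:
  vh:
  - aa: EVQLLESGGGLVQPGGSLRLSCAASGFTF
    nt: GAAGTGCAGCTGCTGGAAAGCGGCGGCGGCCTGGTGCAGCCGGGCGGCAGCCTGCGCCTGAGCTGCGCCGCCAGCGGCTTTACCTTT
  - aa: WVRQAPGKGLEWVS
    nt: TGGGTGCGCCAGGCCCCGGGCAAAGGCCTGGAATGGGTGAGC
  - aa: YYADSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYYCAK
    nt: TATTATGCCGATAGCGTGAAAGGCCGCTTTACCATCAGCCGCGATAACAGCAAAAACACCCTGTATCTGCAGATGAACAGCCTGCGCGCCGAAGATACCGCCGTGTATTATTGCGCCAAA
  - aa: WGQGTLVTVSS
    nt: TGGGGCCAGGGCACCCTGGTGACCGTGAGCAGC
  vl:
  - aa: DIQMTQSPSSLSASVGDRVTITCRASQ
    nt: GATATCCAGATGACCCAGAGCCCGAGCAGCCTGAGCGCCAGCGTGGGCGATCGCGTGACCATCACCTGCCGCGCCAGCCAG
  - aa: WYQQKPGKAPKLLIY
    nt: TGGTATCAGCAGAAACCGGGCAAAGCCCCGAAACTGCTGATCTAT
  - aa: LQSGVPSRFSGSGSGTDFTLTISSLQPEDFATYYC
    nt: CTGCAGAGCGGCGTGCCGAGCCGCTTTAGCGGCAGCGGCAGCGGCACCGATTTTACCCTGACCATCAGCAGCCTGCAGCCGGAAGATTTTGCCACCTATTATTGC
  - aa: TFGQGTKVEIK
    nt: ACCTTTGGCCAGGGCACCAAAGTGGAAATCAAA
linker:
  aa: GGGGSGGGGSGGGGS
  nt: GGCGGCGGCGGCAGCGGCGGCGGCGGCAGCGGCGGCGGCGGCAGC
diversified_positions:
  H1:
  - H30
  - H31
  - H32
  - H33
  - H34
  - H35
  H2:
  - H50
  - H51
  - H52
  - H53
  - H54
  - H55
  - H56
  - H57
  - H58
  L1:
  - L28
  - L29
  - L30
  - L31
  - L32
  - L33
  - L34
  L2:
  - L50
  - L51
  - L52
  - L53
  L3:
  - L89
  - L90
  - L91
  - L92
  - L93
  - L94
  - L95
  - L96
anchors:
  H1:
    prefix: CAASGFTF
    suffix: WVRQAPGK
  H2:
    prefix: GKGLEWVS
    suffix: YYADSVKG
  H3:
    prefix: TAVYYCAK
    suffix: WGQGTLVT
  L1:
    prefix: TITCRASQ
    suffix: WYQQKPGK
  L2:
    prefix: KAPKLLIY
    suffix: LQSGVPSR
  L3:
    prefix: EDFATYYC
    suffix: TFGQGTKV
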