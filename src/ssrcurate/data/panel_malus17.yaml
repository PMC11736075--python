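# Standard 17-marker SSR panel for Malus fingerprinting (ECPGR Malus/Pyrus
# recommendation). Primer sequences are carried as metadata only; they are not
# used in any computation. CH02g09 carries the inter-cohort 2 bp shift rule.
markers:
  - name: CH01h01
    locus_type: single
    forward_primer: GAAAGACTTGCAGTGGGAGC
    reverse_primer: GGAGTGGGTTTGAGAAGGTT
  - name: CH01f07a
    locus_type: single
    forward_primer: CCCTACACAGTTTCTCAACCC
    reverse_primer: CGTTTTTGGAGCGTAGGAAC
  - name: CH03d07
    locus_type: single
    forward_primer: CAAATCAATGCAAAACTGTCA
    reverse_primer: GGCTTCTGGCCATGATTTTA
  - name: CH04c07
    locus_type: single
    forward_primer: GGCCTTCCATGTCTCAGAAG
    reverse_primer: CCTCATGCCCTCCACTAACA
  - name: CH05f06
    locus_type: single
    forward_primer: TTAGATCCGGTCACTCTCCAC
    reverse_primer: TTGGAGGAAGACGAAGAAGAAAG
  - name: CH01f03b
    locus_type: single
    forward_primer: GAGAAGCAAATGCAAAACCC
    reverse_primer: CTCCCCGGCTCCTATTCTAC
  - name: GD12
    locus_type: unknown
    forward_primer: TTGAGGTGTTTCTCCCATTGGA
    reverse_primer: CTAACGAAGCCGCCATTTCTTT
  - name: CH02d08
    locus_type: single
    forward_primer: TCCAAAATGGCGTACCTCTC
    reverse_primer: GCAGACACTCACTCACTATCTCTC
  - name: CH05e03
    locus_type: single
    forward_primer: CGAATATTTTCACTCTGACTGGG
    reverse_primer: CAAGTTGTTGTACTGCTCCGAC
  - name: CH02c09
    locus_type: single
    forward_primer: TTATGTACCAACTTTGCTAACCTC
    reverse_primer: AGAAGCAGCAGAGGAGGATG
  - name: CH02g09
    locus_type: single
    forward_primer: TCAGACAGAAGAGGAACTGTATTTG
    reverse_primer: CAAACAAACCAGTACCGCAA
    shift_rule:
      window_low_bp: 122
      window_high_bp: 140
      shift_bp: 2
      affected_cohort: P2009_2014
  - name: CH01f02
    locus_type: single
    forward_primer: ACCACATTAGAGCAGTTGAGG
    reverse_primer: CTGGTTTGTTTTCCTCCAGC
  - name: CH04f10
    locus_type: single
    forward_primer: GTAATGGAAATACAGTTTCACAATT
    reverse_primer: AAATGCTTGGTGTGTTTTGC
  - name: COL
    locus_type: single
    forward_primer: AGGAGAAAGGCGTTTACCTG
    reverse_primer: GACTCATTCTTCGTCGTCACTG
  - name: Hi02c07
    locus_type: multi
    forward_primer: AGAGCTACGGGGATCCAAAT
    reverse_primer: GTTTAAGCATCCCGATTGAAAGG
  - name: CH04e05
    locus_type: multi
    forward_primer: AGGCTAACAGAAATGTGGTTTG
    reverse_primer: ATGGCTCCTATTGCCATCAT
  - name: GD147
    locus_type: single
    forward_primer: TCCCGCCATTTCTCTGC
    reverse_primer: GTTTAAACCGCTGCTGCTGAAC
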