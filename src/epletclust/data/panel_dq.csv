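bead_id,allele1,allele2
DQA1*01:01~DQB1*05:01,DQA1*01:01,DQB1*05:01
DQA1*01:01~DQB1*06:02,DQA1*01:01,DQB1*06:02
DQA1*01:02~DQB1*05:02,DQA1*01:02,DQB1*05:02
DQA1*01:02~DQB1*06:02,DQA1*01:02,DQB1*06:02
DQA1*01:02~DQB1*06:04,DQA1*01:02,DQB1*06:04
DQA1*01:02~DQB1*06:09,DQA1*01:02,DQB1*06:09
DQA1*01:03~DQB1*06:01,DQA1*01:03,DQB1*06:01
DQA1*01:03~DQB1*06:03,DQA1*01:03,DQB1*06:03
DQA1*02:01~DQB1*04:01,DQA1*02:01,DQB1*04:01
DQA1*02:01~DQB1*04:02,DQA1*02:01,DQB1*04:02
DQA1*03:03~DQB1*04:01,DQA1*03:03,DQB1*04:01
DQA1*04:01~DQB1*04:02,DQA1*04:01,DQB1*04:02
DQA1*02:01~DQB1*03:01,DQA1*02:01,DQB1*03:01
DQA1*02:01~DQB1*03:02,DQA1*02:01,DQB1*03:02
DQA1*02:01~DQB1*03:03,DQA1*02:01,DQB1*03:03
DQA1*03:01~DQB1*03:01,DQA1*03:01,DQB1*03:01
DQA1*03:01~DQB1*03:02,DQA1*03:01,DQB1*03:02
DQA1*03:01~DQB1*03:03,DQA1*03:01,DQB1*03:03
DQA1*03:02~DQB1*03:02,DQA1*03:02,DQB1*03:02
DQA1*03:02~DQB1*03:03,DQA1*03:02,DQB1*03:03
DQA1*05:03~DQB1*03:01,DQA1*05:03,DQB1*03:01
DQA1*05:05~DQB1*03:01,DQA1*05:05,DQB1*03:01
DQA1*06:01~DQB1*03:01,DQA1*06:01,DQB1*03:01
DQA1*02:01~DQB1*02:01,DQA1*02:01,DQB1*02:01
DQA1*02:01~DQB1*02:02,DQA1*02:01,DQB1*02:02
DQA1*03:01~DQB1*02:01,DQA1*03:01,DQB1*02:01
DQA1*04:01~DQB1*02:01,DQA1*04:01,DQB1*02:01
DQA1*05:01~DQB1*02:01,DQA1*05:01,DQB1*02:01
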