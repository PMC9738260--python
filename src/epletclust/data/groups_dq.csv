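bead_id,group
DQA1*01:01~DQB1*05:01,DQ5_6
DQA1*01:01~DQB1*06:02,DQ5_6
DQA1*01:02~DQB1*05:02,DQ5_6
DQA1*01:02~DQB1*06:02,DQ5_6
DQA1*01:02~DQB1*06:04,DQ5_6
DQA1*01:02~DQB1*06:09,DQ5_6
DQA1*01:03~DQB1*06:01,DQ5_6
DQA1*01:03~DQB1*06:03,DQ5_6
DQA1*02:01~DQB1*04:01,DQ4
DQA1*02:01~DQB1*04:02,DQ4
DQA1*03:03~DQB1*04:01,DQ4
DQA1*04:01~DQB1*04:02,DQ4
DQA1*02:01~DQB1*03:01,DQ3
DQA1*02:01~DQB1*03:02,DQ3
DQA1*02:01~DQB1*03:03,DQ3
DQA1*03:01~DQB1*03:01,DQ3
DQA1*03:01~DQB1*03:02,DQ3
DQA1*03:01~DQB1*03:03,DQ3
DQA1*03:02~DQB1*03:02,DQ3
DQA1*03:02~DQB1*03:03,DQ3
DQA1*05:03~DQB1*03:01,DQ3
DQA1*05:05~DQB1*03:01,DQ3
DQA1*06:01~DQB1*03:01,DQ3
DQA1*02:01~DQB1*02:01,DQ2
DQA1*02:01~DQB1*02:02,DQ2
DQA1*03:01~DQB1*02:01,DQ2
DQA1*04:01~DQB1*02:01,DQ2
DQA1*05:01~DQB1*02:01,DQ2
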