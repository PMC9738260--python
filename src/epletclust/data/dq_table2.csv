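allele,eplet,score
DQB1*06:01,3P,High
DQB1*05:01,30H,Intermediate
DQB1*05:02,30H,Intermediate
DQB1*06:04,30H,Intermediate
DQB1*06:03,30H,Intermediate
DQB1*05:01,37YV,High
DQB1*05:02,37YV,High
DQB1*05:01,52PQ,High
DQB1*05:02,52PQ,High
DQB1*06:01,52PQ,High
DQB1*06:02,52PQ,High
DQB1*06:03,52PQ,High
DQB1*06:04,52PQ,High
DQB1*06:09,52PQ,High
DQB1*06:01,55RPD,High
DQB1*06:02,55RPD,High
DQB1*06:03,55RPD,High
DQB1*05:02,56PS,High
DQB1*05:01,57V,High
DQB1*06:04,57V,High
DQB1*06:09,57V,High
DQB1*05:01,67VG,High
DQB1*05:02,67VG,High
DQB1*06:02,67VG,High
DQB1*06:03,67VG,High
DQB1*06:02,70GT,High
DQB1*06:03,70GT,High
DQB1*05:01,86A,Intermediate
DQB1*05:02,86A,Intermediate
DQB1*06:01,86A,Intermediate
DQB1*06:02,86A,Intermediate
DQB1*06:03,86A,Intermediate
DQB1*06:01,87F,High
DQB1*06:02,87F,High
DQB1*06:03,87F,High
DQB1*05:01,87Y,Intermediate
DQB1*05:02,87Y,Intermediate
DQB1*06:04,87Y,Intermediate
DQB1*06:09,87Y,Intermediate
DQB1*05:01,116I,High
DQB1*05:02,116I,High
DQB1*06:01,125G,VeryLow
DQB1*06:02,125G,VeryLow
DQB1*06:03,125G,VeryLow
DQB1*06:04,125G,VeryLow
DQB1*06:09,125G,VeryLow
DQB1*05:01,125SQ,Low
DQB1*06:04,130Q,Intermediate
DQB1*06:09,130Q,Intermediate
DQA1*01:01,52SK,High
DQA1*01:02,52SK,High
DQA1*01:03,52SK,High
DQA1*01:01,129QS,High
DQA1*01:02,129QS,High
DQA1*01:03,130A,High
DQB1*04:01,23L,High
DQB1*04:01,56L,High
DQB1*04:02,56L,High
DQB1*03:01,45EV,High
DQB1*03:01,55PP,High
DQB1*03:02,55PP,High
DQB1*03:03,55PP,High
DQB1*03:02,55PPA,High
DQB1*03:01,55PPD,High
DQB1*03:03,55PPD,High
DQA1*05:03,160S,High
DQB1*02:01,52LL,High
DQB1*02:02,52LL,High
DQB1*02:02,135G,High
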