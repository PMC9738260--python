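bead_id,group
DRB1*01:01,C
DRB1*01:02,C
DRB1*01:03,C
DRB1*09:01,C
DRB1*09:02,C
DRB1*10:01,C
DRB1*15:01,C
DRB1*15:02,C
DRB1*15:03,C
DRB1*16:01,C
DRB1*16:02,C
DRB5*01:01,C
DRB5*02:02,C
DRB1*04:01,B
DRB1*04:02,B
DRB1*04:03,B
DRB1*04:04,B
DRB1*04:05,B
DRB1*07:01,B
DRB4*01:01,B
DRB4*01:03,B
DRB1*03:01,A
DRB1*03:02,A
DRB1*08:01,A
DRB1*11:01,A
DRB1*11:04,A
DRB1*12:01,A
DRB1*12:02,A
DRB1*13:01,A
DRB1*13:03,A
DRB1*14:01,A
DRB1*14:02,A
DRB1*14:54,A
DRB3*01:01,A
DRB3*02:02,A
DRB3*03:01,A
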