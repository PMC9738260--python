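bead_id,allele1,allele2
DRB1*01:01,DRB1*01:01,
DRB1*01:02,DRB1*01:02,
DRB1*01:03,DRB1*01:03,
DRB1*09:01,DRB1*09:01,
DRB1*09:02,DRB1*09:02,
DRB1*10:01,DRB1*10:01,
DRB1*15:01,DRB1*15:01,
DRB1*15:02,DRB1*15:02,
DRB1*15:03,DRB1*15:03,
DRB1*16:01,DRB1*16:01,
DRB1*16:02,DRB1*16:02,
DRB5*01:01,DRB5*01:01,
DRB5*02:02,DRB5*02:02,
DRB1*04:01,DRB1*04:01,
DRB1*04:02,DRB1*04:02,
DRB1*04:03,DRB1*04:03,
DRB1*04:04,DRB1*04:04,
DRB1*04:05,DRB1*04:05,
DRB1*07:01,DRB1*07:01,
DRB4*01:01,DRB4*01:01,
DRB4*01:03,DRB4*01:03,
DRB1*03:01,DRB1*03:01,
DRB1*03:02,DRB1*03:02,
DRB1*08:01,DRB1*08:01,
DRB1*11:01,DRB1*11:01,
DRB1*11:04,DRB1*11:04,
DRB1*12:01,DRB1*12:01,
DRB1*12:02,DRB1*12:02,
DRB1*13:01,DRB1*13:01,
DRB1*13:03,DRB1*13:03,
DRB1*14:01,DRB1*14:01,
DRB1*14:02,DRB1*14:02,
DRB1*14:54,DRB1*14:54,
DRB3*01:01,DRB3*01:01,
DRB3*02:02,DRB3*02:02,
DRB3*03:01,DRB3*03:01,
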