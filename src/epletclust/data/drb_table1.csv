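allele,eplet,score
DRB5*02:02,6C,High
DRB1*01:01,13FE,VeryLow
DRB1*01:02,13FE,VeryLow
DRB1*01:03,13FE,VeryLow
DRB1*09:01,13FE,VeryLow
DRB1*09:02,13FE,VeryLow
DRB1*09:01,28H,Low
DRB1*09:02,28H,Low
DRB5*01:01,28H,Low
DRB5*02:02,28H,Low
DRB1*01:01,30C,Intermediate
DRB1*01:02,30C,Intermediate
DRB1*01:03,30C,Intermediate
DRB5*01:01,30D,Intermediate
DRB1*09:01,30G,Intermediate
DRB1*09:02,30G,Intermediate
DRB5*02:02,30G,Intermediate
DRB1*10:01,30RV,Intermediate
DRB1*01:01,37S,High
DRB1*01:02,37S,High
DRB1*01:03,37S,High
DRB1*15:01,37S,High
DRB1*15:02,37S,High
DRB1*15:03,37S,High
DRB1*16:01,37S,High
DRB1*16:02,37S,High
DRB1*15:01,71A,Intermediate
DRB1*15:02,71A,Intermediate
DRB1*15:03,71A,Intermediate
DRB5*02:02,71A,Intermediate
DRB1*01:01,96EV,High
DRB1*01:02,96EV,High
DRB1*01:03,96EV,High
DRB5*01:01,96EV,High
DRB5*02:02,96EV,High
DRB5*01:01,108T,High
DRB5*02:02,108T,High
DRB1*15:01,142M,High
DRB1*15:02,142M,High
DRB1*15:03,142M,High
DRB1*16:01,142M,High
DRB1*16:02,142M,High
DRB1*07:01,25Q,Intermediate
DRB4*01:01,48Q,High
DRB4*01:03,48Q,High
DRB1*04:01,96Y,High
DRB1*04:02,96Y,High
DRB1*04:03,96Y,High
DRB1*04:04,96Y,High
DRB1*04:05,96Y,High
DRB1*03:01,11STS,Intermediate
DRB1*03:02,11STS,Intermediate
DRB1*11:01,11STS,Intermediate
DRB1*11:04,11STS,Intermediate
DRB1*13:01,11STS,Intermediate
DRB1*13:03,11STS,Intermediate
DRB1*14:01,11STS,Intermediate
DRB1*14:02,11STS,Intermediate
DRB1*14:54,11STS,Intermediate
DRB1*03:01,13SE,VeryLow
DRB1*03:02,13SE,VeryLow
DRB1*11:01,13SE,VeryLow
DRB1*11:04,13SE,VeryLow
DRB1*13:01,13SE,VeryLow
DRB1*13:03,13SE,VeryLow
DRB1*14:01,13SE,VeryLow
DRB1*14:02,13SE,VeryLow
DRB1*14:54,13SE,VeryLow
DRB3*01:01,13SE,VeryLow
DRB3*02:02,13SE,VeryLow
DRB3*03:01,13SE,VeryLow
DRB1*08:01,16Y,Low
DRB1*12:01,16Y,Low
DRB1*12:02,16Y,Low
DRB1*03:01,31FH,High
DRB1*03:02,31FH,High
DRB1*12:01,31FH,High
DRB1*12:02,31FH,High
DRB1*13:01,31FH,High
DRB1*14:01,31FH,High
DRB1*14:02,31FH,High
DRB1*14:54,31FH,High
DRB3*01:01,31FH,High
DRB3*02:02,31FH,High
DRB3*03:01,31FH,High
DRB3*01:01,37FL,High
DRB1*12:01,37L,High
DRB1*12:02,37L,High
DRB3*02:02,51R,High
DRB1*14:01,57A,High
DRB1*14:54,57A,High
DRB1*11:01,57DE,High
DRB1*11:04,57DE,High
DRB3*02:02,70QQ,High
DRB3*03:01,70QQ,High
DRB1*08:01,74L,High
DRB1*03:01,74R,High
DRB1*03:02,74R,High
DRB3*01:01,74R,High
DRB1*03:01,77N,High
DRB1*03:02,77N,High
DRB3*01:01,77N,High
DRB3*02:02,77N,High
DRB3*03:01,77N,High
DRB1*03:01,96HK,
DRB1*03:02,96HK,
DRB1*08:01,96HK,
DRB1*11:01,96HK,
DRB1*11:04,96HK,
DRB1*12:01,96HK,
DRB1*12:02,96HK,
DRB1*13:01,96HK,
DRB1*14:01,96HK,
DRB1*14:02,96HK,
DRB1*14:54,96HK,
DRB3*01:01,98Q,Intermediate
DRB3*02:02,98Q,Intermediate
DRB3*03:01,98Q,Intermediate
DRB1*14:01,112Y,High
DRB1*03:01,149H,VeryLow
DRB1*03:02,149H,VeryLow
DRB1*08:01,149H,VeryLow
DRB1*11:01,149H,VeryLow
DRB1*11:04,149H,VeryLow
DRB1*12:01,149H,VeryLow
DRB1*12:02,149H,VeryLow
DRB1*13:01,149H,VeryLow
DRB1*14:01,149H,VeryLow
DRB1*14:02,149H,VeryLow
DRB1*14:54,149H,VeryLow
DRB3*03:01,149H,VeryLow
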