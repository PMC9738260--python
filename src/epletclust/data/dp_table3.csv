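allele,eplet,score
DPB1*02:01,84GGPM,High
DPB1*04:01,84GGPM,High
DPB1*04:02,84GGPM,High
DPB1*23:01,84GGPM,High
DPB1*04:02,178M,High
DPB1*09:01,9H,Low
DPB1*10:01,9H,Low
DPB1*14:01,9H,Low
DPB1*17:01,9H,Low
DPB1*03:01,9YL,Low
DPB1*06:01,9YL,Low
DPB1*11:01,9YL,Low
DPB1*13:01,9YL,Low
DPB1*20:01,9YL,Low
DPB1*03:01,11L,VeryLow
DPB1*06:01,11L,VeryLow
DPB1*09:01,11L,VeryLow
DPB1*10:01,11L,VeryLow
DPB1*11:01,11L,VeryLow
DPB1*13:01,11L,VeryLow
DPB1*14:01,11L,VeryLow
DPB1*17:01,11L,VeryLow
DPB1*20:01,11L,VeryLow
DPB1*01:01,33EYA,High
DPB1*13:01,33EYA,High
DPB1*05:01,35LV,High
DPB1*01:01,35YA,High
DPB1*11:01,35YA,High
DPB1*13:01,35YA,High
DPB1*15:01,35YA,High
DPB1*05:01,55EAE,High
DPB1*19:01,55EAE,High
DPB1*03:01,57D,High
DPB1*06:01,57D,High
DPB1*09:01,57D,High
DPB1*14:01,57D,High
DPB1*17:01,57D,High
DPB1*20:01,57D,High
DPB1*06:01,65LE,High
DPB1*11:01,69R,High
DPB1*15:01,69R,High
DPB1*13:01,76I,Intermediate
DPB1*19:01,76I,Intermediate
DPB1*01:01,76V,Intermediate
DPB1*03:01,76V,Intermediate
DPB1*09:01,76V,Intermediate
DPB1*10:01,76V,Intermediate
DPB1*14:01,76V,Intermediate
DPB1*01:01,84DEAV,High
DPB1*03:01,84DEAV,High
DPB1*05:01,84DEAV,High
DPB1*06:01,84DEAV,High
DPB1*09:01,84DEAV,High
DPB1*10:01,84DEAV,High
DPB1*11:01,84DEAV,High
DPB1*13:01,84DEAV,High
DPB1*14:01,84DEAV,High
DPB1*17:01,84DEAV,High
DPB1*20:01,84DEAV,High
DPA1*02:02,11M,VeryLow
DPA1*03:01,11M,VeryLow
DPA1*02:01,31Q,VeryLow
DPA1*02:02,31Q,VeryLow
DPA1*02:01,50R,High
DPA1*02:02,50R,High
DPA1*04:01,50R,High
DPA1*03:01,66S,High
DPA1*02:01,111R,Low
DPA1*02:02,111R,Low
DPA1*02:01,127P,High
DPA1*02:02,127P,High
DPA1*04:01,127P,High
DPA1*02:01,160V,High
DPA1*02:02,160V,High
DPA1*04:01,160V,High
DPA1*04:01,190A,High
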