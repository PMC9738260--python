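bead_id,group
DPA1*01:03~DPB1*02:01,upper
DPA1*01:03~DPB1*04:02,upper
DPA1*01:03~DPB1*28:01,upper
DPA1*01:04~DPB1*18:01,upper
DPA1*01:05~DPB1*18:01,upper
DPA1*01:05~DPB1*28:01,upper
DPA1*01:03~DPB1*04:01,upper
DPA1*01:03~DPB1*23:01,upper
DPA1*01:03~DPB1*01:01,lower
DPA1*01:03~DPB1*03:01,lower
DPA1*01:03~DPB1*06:01,lower
DPA1*01:03~DPB1*11:01,lower
DPA1*01:03~DPB1*19:01,lower
DPA1*01:05~DPB1*03:01,lower
DPA1*02:01~DPB1*01:01,lower
DPA1*02:01~DPB1*03:01,lower
DPA1*02:01~DPB1*05:01,lower
DPA1*02:01~DPB1*06:01,lower
DPA1*02:01~DPB1*09:01,lower
DPA1*02:01~DPB1*10:01,lower
DPA1*02:01~DPB1*13:01,lower
DPA1*02:01~DPB1*14:01,lower
DPA1*02:01~DPB1*15:01,lower
DPA1*02:01~DPB1*18:01,lower
DPA1*02:01~DPB1*17:01,lower
DPA1*02:02~DPB1*05:01,lower
DPA1*02:02~DPB1*10:01,lower
DPA1*02:02~DPB1*11:01,lower
DPA1*02:02~DPB1*13:01,lower
DPA1*03:01~DPB1*13:01,lower
DPA1*03:01~DPB1*20:01,lower
DPA1*04:01~DPB1*28:01,lower
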