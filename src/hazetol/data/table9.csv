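index,number of microblogs,correlation coefficient of number,sentiment score,correlation coefficient of sentiment,topic index
number of microblogs,1,0.31582,0.166667,0.45225,0.12424
correlation coefficient of number,3.16636,1,0.65392,1.1,0.16667
sentiment score,6,1.52924,1,1.27,0.72737
correlation coefficient of sentiment,2.21116,0.90909,0.7874,1,1.1
topic index,8.04894,6,1.37482,0.90909,1
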