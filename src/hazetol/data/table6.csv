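index,ecological environment,social economy,social media
ecological environment,1,4,0.33333
social economy,0.25,1,0.14286
social media,3,7,1
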