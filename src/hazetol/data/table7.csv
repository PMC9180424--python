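index,temperature,air quality,relative humidity,wind speed,pollution days
temperature,1,5.95733,5.37924,6,1
air quality,0.16786,1,0.36,2.35832,0.34832
relative humidity,0.18591,2.77778,1,2.63424,0.13234
wind speed,0.166667,0.42399,0.37962,1,0.16982
pollution days,1,2.87092,7.55629,5.88859,1
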