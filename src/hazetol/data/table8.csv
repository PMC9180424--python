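index,population density,per capita GDP,proportion of secondary industry,proportion of built-up area,road area,per capita green space area,education level,gender ratio
population density,1,0.68472,0.15402,0.65873,0.52938,0.62348,0.31245,0.53981
per capita GDP,1.46045,1,0.28564,2.43921,2.32913,0.31569,0.29837,2.4
proportion of secondary industry,6.49284,3.50091,1,2.5,1,2.47921,2.68931,2.78931
proportion of built-up area,1.51807,0.40997,0.4,1,0.5,0.33333,0.57532,0.5
road area,1.88901,0.42934,1,2,1,0.7,0.65,2.63922
per capita green space area,1.60391,3.16766,0.40335,3,1.42857,1,2.42324,2.58482
education level,3.20051,3.35154,0.37184,1.73816,1.53846,0.41267,1,2.35382
gender ratio,1.8525,0.41667,0.35851,2,0.37879,0.38687,0.42484,1
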