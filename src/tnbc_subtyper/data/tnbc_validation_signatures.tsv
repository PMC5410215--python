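subtype	direction	gene
IM	up	232362_at
IM	up	206486_at
IM	up	207634_at
IM	up	223834_at
IM	up	220049_s_at
IM	up	222835_at
IM	up	228708_at
IM	up	209505_at
IM	up	226553_at
IM	up	213823_at
MSL	up	227427_at
MSL	up	206485_at
MSL	up	217190_x_at
MSL	up	211233_x_at
MSL	up	215104_at
MSL	up	229377_at
MSL	up	244264_at
MSL	up	232179_at
MSL	up	236390_at
MSL	up	232001_at
M	up	201268_at
M	up	213801_x_at
M	up	200023_s_at
M	up	215157_x_at
M	up	228256_s_at
M	up	205990_s_at
M	up	226192_at
M	up	204014_at
M	up	203963_at
LAR	up	218211_s_at
LAR	up	215465_s_at
LAR	up	232914_s_at
LAR	up	212510_at
LAR	up	227733_at
LAR	up	235020_at
LAR	up	209138_x_at
LAR	up	225973_at
LAR	up	223307_at
BL	up	219787_s_at
BL	up	231984_at
BL	up	229538_s_at
BL	up	208165_s_at
BL	up	226189_at
BL	up	212998_x_at
BL	up	215536_at
BL	up	204149_s_at
BL	up	214123_s_at
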