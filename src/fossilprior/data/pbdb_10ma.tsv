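# Uniform 10 Ma stratigraphic bins spanning the Phanerozoic (540-0 Ma),
# in the style of the Paleobiology Database 10 Myr binning. Bin names give
# the age bounds in Ma.
name	older_bound	younger_bound
bin_10_0	10	0
bin_20_10	20	10
bin_30_20	30	20
bin_40_30	40	30
bin_50_40	50	40
bin_60_50	60	50
bin_70_60	70	60
bin_80_70	80	70
bin_90_80	90	80
bin_100_90	100	90
bin_110_100	110	100
bin_120_110	120	110
bin_130_120	130	120
bin_140_130	140	130
bin_150_140	150	140
bin_160_150	160	150
bin_170_160	170	160
bin_180_170	180	170
bin_190_180	190	180
bin_200_190	200	190
bin_210_200	210	200
bin_220_210	220	210
bin_230_220	230	220
bin_240_230	240	230
bin_250_240	250	240
bin_260_250	260	250
bin_270_260	270	260
bin_280_270	280	270
bin_290_280	290	280
bin_300_290	300	290
bin_310_300	310	300
bin_320_310	320	310
bin_330_320	330	320
bin_340_330	340	330
bin_350_340	350	340
bin_360_350	360	350
bin_370_360	370	360
bin_380_370	380	370
bin_390_380	390	380
bin_400_390	400	390
bin_410_400	410	400
bin_420_410	420	410
bin_430_420	430	420
bin_440_430	440	430
bin_450_440	450	440
bin_460_450	460	450
bin_470_460	470	460
bin_480_470	480	470
bin_490_480	490	480
bin_500_490	500	490
bin_510_500	510	500
bin_520_510	520	510
bin_530_520	530	520
bin_540_530	540	530
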