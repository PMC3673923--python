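# International Stratigraphic Commission stages with the 2004 geologic
# timescale calibration of absolute ages (Ma): the calibration used by the
# method's reference applications (e.g. Wuchiapingian base 260.4 Ma,
# Hettangian base 199.6 Ma).  Quaternary subseries and Cambrian series are
# carried as informal stage-rank bins.  Stage boundary ages are revised over
# time; the ISC_stages_2013 scheme carries a later calibration, and a custom
# table may be supplied to override ages.
name	older_bound	younger_bound
Holocene	0.0115	0.0
Upper_Pleistocene	0.126	0.0115
Middle_Pleistocene	0.781	0.126
Lower_Pleistocene	1.806	0.781
Gelasian	2.588	1.806
Piacenzian	3.6	2.588
Zanclean	5.332	3.6
Messinian	7.246	5.332
Tortonian	11.608	7.246
Serravallian	13.65	11.608
Langhian	15.97	13.65
Burdigalian	20.43	15.97
Aquitanian	23.03	20.43
Chattian	28.4	23.03
Rupelian	33.9	28.4
Priabonian	37.2	33.9
Bartonian	40.4	37.2
Lutetian	48.6	40.4
Ypresian	55.8	48.6
Thanetian	58.7	55.8
Selandian	61.7	58.7
Danian	65.5	61.7
Maastrichtian	70.6	65.5
Campanian	83.5	70.6
Santonian	85.8	83.5
Coniacian	89.3	85.8
Turonian	93.5	89.3
Cenomanian	99.6	93.5
Albian	112.0	99.6
Aptian	125.0	112.0
Barremian	130.0	125.0
Hauterivian	136.4	130.0
Valanginian	140.2	136.4
Berriasian	145.5	140.2
Tithonian	150.8	145.5
Kimmeridgian	155.7	150.8
Oxfordian	161.2	155.7
Callovian	164.7	161.2
Bathonian	167.7	164.7
Bajocian	171.6	167.7
Aalenian	175.6	171.6
Toarcian	183.0	175.6
Pliensbachian	189.6	183.0
Sinemurian	196.5	189.6
Hettangian	199.6	196.5
Rhaetian	203.6	199.6
Norian	216.5	203.6
Carnian	228.0	216.5
Ladinian	237.0	228.0
Anisian	245.0	237.0
Olenekian	249.7	245.0
Induan	251.0	249.7
Changhsingian	253.8	251.0
Wuchiapingian	260.4	253.8
Capitanian	265.8	260.4
Wordian	268.0	265.8
Roadian	270.6	268.0
Kungurian	275.6	270.6
Artinskian	284.4	275.6
Sakmarian	294.6	284.4
Asselian	299.0	294.6
Gzhelian	303.9	299.0
Kasimovian	306.5	303.9
Moscovian	311.7	306.5
Bashkirian	318.1	311.7
Serpukhovian	326.4	318.1
Visean	345.3	326.4
Tournaisian	359.2	345.3
Famennian	374.5	359.2
Frasnian	385.3	374.5
Givetian	391.8	385.3
Eifelian	397.5	391.8
Emsian	407.0	397.5
Pragian	411.2	407.0
Lochkovian	416.0	411.2
Pridoli	418.7	416.0
Ludfordian	421.3	418.7
Gorstian	422.9	421.3
Homerian	426.2	422.9
Sheinwoodian	428.2	426.2
Telychian	436.0	428.2
Aeronian	439.0	436.0
Rhuddanian	443.7	439.0
Hirnantian	445.6	443.7
Katian	455.8	445.6
Sandbian	460.9	455.8
Darriwilian	468.1	460.9
Dapingian	471.8	468.1
Floian	478.6	471.8
Tremadocian	488.3	478.6
Furongian	501.0	488.3
Cambrian_Series3	513.0	501.0
Cambrian_Series2	528.0	513.0
Terreneuvian	542.0	528.0
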