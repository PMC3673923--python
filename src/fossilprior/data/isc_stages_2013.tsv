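# International Chronostratigraphic Chart, Phanerozoic stages (v2013/01 ages, Ma).
# Quaternary subdivisions are listed at stage rank (Tarantian/Ionian informal).
# Stage boundary ages are revised periodically; override with a custom table
# if a different calibration of absolute ages is required.
name	older_bound	younger_bound
Holocene	0.0117	0
Tarantian	0.126	0.0117
Ionian	0.781	0.126
Calabrian	1.806	0.781
Gelasian	2.588	1.806
Piacenzian	3.6	2.588
Zanclean	5.333	3.6
Messinian	7.246	5.333
Tortonian	11.63	7.246
Serravallian	13.82	11.63
Langhian	15.97	13.82
Burdigalian	20.44	15.97
Aquitanian	23.03	20.44
Chattian	28.1	23.03
Rupelian	33.9	28.1
Priabonian	37.8	33.9
Bartonian	41.2	37.8
Lutetian	47.8	41.2
Ypresian	56.0	47.8
Thanetian	59.2	56.0
Selandian	61.6	59.2
Danian	66.0	61.6
Maastrichtian	72.1	66.0
Campanian	83.6	72.1
Santonian	86.3	83.6
Coniacian	89.8	86.3
Turonian	93.9	89.8
Cenomanian	100.5	93.9
Albian	113.0	100.5
Aptian	125.0	113.0
Barremian	129.4	125.0
Hauterivian	132.9	129.4
Valanginian	139.8	132.9
Berriasian	145.0	139.8
Tithonian	152.1	145.0
Kimmeridgian	157.3	152.1
Oxfordian	163.5	157.3
Callovian	166.1	163.5
Bathonian	168.3	166.1
Bajocian	170.3	168.3
Aalenian	174.1	170.3
Toarcian	182.7	174.1
Pliensbachian	190.8	182.7
Sinemurian	199.3	190.8
Hettangian	201.3	199.3
Rhaetian	208.5	201.3
Norian	227.0	208.5
Carnian	237.0	227.0
Ladinian	242.0	237.0
Anisian	247.2	242.0
Olenekian	251.2	247.2
Induan	252.2	251.2
Changhsingian	254.1	252.2
Wuchiapingian	259.8	254.1
Capitanian	265.1	259.8
Wordian	268.8	265.1
Roadian	272.3	268.8
Kungurian	283.5	272.3
Artinskian	290.1	283.5
Sakmarian	295.0	290.1
Asselian	298.9	295.0
Gzhelian	303.7	298.9
Kasimovian	307.0	303.7
Moscovian	315.2	307.0
Bashkirian	323.2	315.2
Serpukhovian	330.9	323.2
Visean	346.7	330.9
Tournaisian	358.9	346.7
Famennian	372.2	358.9
Frasnian	382.7	372.2
Givetian	387.7	382.7
Eifelian	393.3	387.7
Emsian	407.6	393.3
Pragian	410.8	407.6
Lochkovian	419.2	410.8
Pridoli	423.0	419.2
Ludfordian	425.6	423.0
Gorstian	427.4	425.6
Homerian	430.5	427.4
Sheinwoodian	433.4	430.5
Telychian	438.5	433.4
Aeronian	440.8	438.5
Rhuddanian	443.8	440.8
Hirnantian	445.2	443.8
Katian	453.0	445.2
Sandbian	458.4	453.0
Darriwilian	467.3	458.4
Dapingian	470.0	467.3
Floian	477.7	470.0
Tremadocian	485.4	477.7
Stage_10	489.5	485.4
Jiangshanian	494.0	489.5
Paibian	497.0	494.0
Guzhangian	500.5	497.0
Drumian	504.5	500.5
Wuliuan	509.0	504.5
Stage_4	514.0	509.0
Stage_3	521.0	514.0
Stage_2	529.0	521.0
Fortunian	541.0	529.0
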