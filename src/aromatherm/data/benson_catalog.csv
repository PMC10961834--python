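group,benson_g,new_g,benson_cr,new_cr
CO-(O)(CO),-123.75,-82.19,-120.81,-108.4
CO-(CD)(O),-136.73,18.98,-134.1,
CO-(C)(O),-137.24,-79.59,-153.6,-101.62
CO-(H)(O),-124.39,0,,
CO-(O)(CB),-125.0,-44.64,-145.0,-37.98
O-(H)(CO),-254.3,-187.44,-282.15,-248.0
O-(C)(CB),-92.55,-18.21,-122.87,-6.83
CD-(H)(CO),32.3,18.98,7.82,
CB-(CO)(CB)2,15.5,-44.64,8.15,-37.98
CB-(O)(CB)2,-4.75,-18.21,1.0,-71.31
C-(CO)(C)3,23.93,-24.93,24.02,-75.39
C-(H)2(CO)(C),-21.84,-38.03,-27.9,-55.35
C-(H)3(O),-42.26,-18.21,-46.74,-6.83
C-(H)3(C),-42.26,49.39,-46.74,-4.37
C-(H)3(CB),,45.32,-18.17,
C-(H)2(C)2,-20.63,-21.15,-29.41,-27.6
CD-(H)2,26.32,18.98,22.43,
CB-(H)(CB)2,13.81,38.41,6.53,11.13
CB-(C)(CB)2,23.64,18.91,13.9,18.79
C-(H)2(C)(CB),-21.34,-26.41,-22.1,0.61
CH3(qua),-4.56,-49.86,-4.35,0.53
O-(H)(CB),-160.3,,-199.25,-64.48
C-(H)(CO)(C)2,-0.25,,-9.83,-82.31
C-(H)(C)3,-1.17,,-5.98,16.73
CH3(tert),-2.26,,-2.34,-0.03
O-(H)(C),-159.33,,-199.66,-105.79
C-(H)2(CO)2,-30.74,,-19.1,-74.85
C-(H)(O)(CO)(C),126.63,,-14.39,-105.79
radical 1,,-21.59,,-5.75
radical 2,,-2.19,,-5.2
radical 3,,-8.74,,-9.74
radical 4,,-7.27,,-8.11
correction 1,,0.92,,39.51
correction 1 meta,,-2.28,,-14.2
correction 1 ortho,,-14.84,,-6.77
correction 1 para,,16.19,,-18.54
correction 2,,34.31,,24.82
correction 2 meta,,-16.64,,-12.74
correction 2 ortho,,0,,6.62
correction 2 para,,-17.67,,-18.7
correction 3,,6.58,,10.03
correction 3 meta,,-5.75,,-10.55
correction 3 ortho,,11.66,,20.47
correction 3 para,,-12.49,,-19.94
correction 4,,1.21,,2.92
correction 4 meta,,0,,-9.4
correction 4 ortho,,-1.21,,6.48
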