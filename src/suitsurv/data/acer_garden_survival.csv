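species,section,native_to,KEW,RBGE,WESB
A. crataegifolium,Macrantha,Asia,0.43,0.25,0.40
A. davidii,Macrantha,Asia,0.46,0.55,0.59
A. rufinerve,Macrantha,Asia,0.57,0.73,0.67
A. pensylvanicum,Macrantha,America,0.29,0.48,0.59
A. tschonoskii,Macrantha,Asia,,,0.62
A. campbellii,Palmata,Asia,,0.76,0.75
A. circinatum,Palmata,America,,0.86,0.71
A. japonicum,Palmata,Asia,1.00,0.87,0.73
A. palmatum,Palmata,Asia,0.87,0.70,0.61
A. campestre,Platanoidea,Europe,0.84,1.00,1.00
A. platanoides,Platanoidea,Europe,0.75,0.86,0.85
A. cappadocicum,Platanoidea,Asia,0.91,0.84,0.86
A. pictum,Platanoidea,Asia,0.73,0.70,0.95
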