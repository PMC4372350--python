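# Default feature template set (CRF++-style U/B grammar).
# Columns: 0=PRIMARY 1=SS 2=DOMAIN 3=ALIGN 4=AMPA 5=AGGR 6=CHARGE 7=AMPH
# Unigram (state) features: every channel at every offset of the size-5 window.
U000:%x[-2,0]
U001:%x[-1,0]
U002:%x[0,0]
U003:%x[1,0]
U004:%x[2,0]
U010:%x[-2,1]
U011:%x[-1,1]
U012:%x[0,1]
U013:%x[1,1]
U014:%x[2,1]
U020:%x[-2,2]
U021:%x[-1,2]
U022:%x[0,2]
U023:%x[1,2]
U024:%x[2,2]
U030:%x[-2,3]
U031:%x[-1,3]
U032:%x[0,3]
U033:%x[1,3]
U034:%x[2,3]
U040:%x[-2,4]
U041:%x[-1,4]
U042:%x[0,4]
U043:%x[1,4]
U044:%x[2,4]
U050:%x[-2,5]
U051:%x[-1,5]
U052:%x[0,5]
U053:%x[1,5]
U054:%x[2,5]
U060:%x[-2,6]
U061:%x[-1,6]
U062:%x[0,6]
U063:%x[1,6]
U064:%x[2,6]
U070:%x[-2,7]
U071:%x[-1,7]
U072:%x[0,7]
U073:%x[1,7]
U074:%x[2,7]
# Residue bigram on the primary structure.
U100:%x[-1,0]/%x[0,0]
# Pure label-transition feature.
B
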