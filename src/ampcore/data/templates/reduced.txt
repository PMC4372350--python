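# Reduced feature template set: PRIMARY keeps the full size-5 window, the
# derived channels fire at the focus position only. Faster to train; used for
# moderate-sized corpora.
# Columns: 0=PRIMARY 1=SS 2=DOMAIN 3=ALIGN 4=AMPA 5=AGGR 6=CHARGE 7=AMPH
U000:%x[-2,0]
U001:%x[-1,0]
U002:%x[0,0]
U003:%x[1,0]
U004:%x[2,0]
U012:%x[0,1]
U022:%x[0,2]
U032:%x[0,3]
U042:%x[0,4]
U052:%x[0,5]
U062:%x[0,6]
U072:%x[0,7]
U100:%x[-1,0]/%x[0,0]
B
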