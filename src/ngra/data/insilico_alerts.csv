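profiler,source_call,target_call
DART scheme,Known precedent reproductive and developmental toxic potential,Known precedent reproductive and developmental toxic potential
ER binding,"Very strong binder, OH group; non-steroid nucleus derived ER and AR; flavone and mycoestrogen related derivatives (2b-1)","Very strong binder, OH group; non-steroid nucleus derived ER and AR; flavone and mycoestrogen related derivatives (2b-1)"
Retinoic acid receptor binding,Not possible to classify according to these rules,Not possible to classify according to these rules
rtER expert system US EPA,No alert found,No alert found
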